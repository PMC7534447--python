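"""CpG[o/e] methylation signature and mixture-component selection.

Simulates coding sequences whose CpG depletion follows a trimodal
mixture (a low mode is the classic footprint of germline DNA
methylation), computes per-gene CpG[o/e], and asks how many mixture
components the distribution supports via BIC over univariate Gaussian
mixtures (equal- and free-variance families, k = 1..5).
"""

import vespagen as vg

spec = vg.CpGSimSpec(
    components=((1 / 3, 0.35, 0.05), (1 / 3, 0.65, 0.05), (1 / 3, 0.95, 0.05)),
    n_genes=1500,
    gene_length_law=("constant", 4000),
    seed=3,
)
genes, truth = vg.simulate_cpg_genes(spec)
table = vg.cpg_table(genes)  # length-normalised o/e by default
values = table.defined_values()
print(f"genes             {len(values)} (CpG[o/e] defined for all)")
print(f"mean CpG[o/e]     {values.mean():.3f}")

selection = vg.select_components(values, k_max=5, seed=1)
best = selection.selected
print(f"selected k        {best.k} ({best.family})")
for w, m, s in zip(best.weights, best.means, best.sds):
    print(f"  component: weight {w:.2f}  mean {m:.3f}  sd {s:.3f}")
print()
print(
    "BIC (2 logL - p ln n, larger is better) prefers three components,\n"
    "recovering the planted trimodal structure; the low-CpG[o/e] mode is\n"
    "what historical germline methylation leaves in real gene sets."
)
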