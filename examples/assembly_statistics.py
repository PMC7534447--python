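"""Summary statistics for a genome assembly.

Simulates a small wasp-like assembly (soft-masked repeats, N gaps), then
computes the statistics a genome report tabulates: total sequence,
largest scaffold, scaffold count, N50, N bases, gap runs and the
soft-masked repeat fraction.
"""

import vespagen as vg

assembly, truth, _, _ = vg.simulate_assembly(vg.AssemblySimSpec(seed=1))
stats = vg.compute_stats(assembly)

print(f"scaffolds        {stats.n_scaffolds}")
print(f"total sequence   {stats.total_length:,} bp")
print(f"largest          {stats.largest:,} bp")
print(f"N50              {stats.n50:,} bp")
print(f"Ns               {stats.n_count:,}")
print(f"gaps (N runs)    {stats.gap_count}")
print(f"repeats          {100 * stats.repeat_fraction:.2f}%")
print()
print(
    "N50 is the largest scaffold length L such that scaffolds >= L cover\n"
    "half the assembly; the repeat percentage is read from lowercase\n"
    "(soft-masked) bases, matching the planted "
    f"{100 * truth['mask_fraction'].mean():.1f}% mask fraction."
)
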