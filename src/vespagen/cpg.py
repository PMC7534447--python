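"""Per-gene CpG observed/expected ratios and mixture-component selection.

CpG[o/e] measures depletion of the CG dinucleotide relative to the
expectation under base-composition independence.  Methylated cytosines in
a CpG context deaminate to thymine over evolutionary time, so genes that
have been germline-methylated show CpG[o/e] well below 1; a multimodal
CpG[o/e] distribution across genes is the classic sequence signature of
targeted DNA methylation in insects.

Two normalisations are offered:

* ``literal``:            n_CpG / (n_C * n_G)
* ``length_normalized``:  n_CpG * L / (n_C * n_G)   (default)

The literal ratio scales as 1/L and is only comparable between
equal-length sequences; the length-normalised form is the standard
observed/expected ratio with expectation (n_C/L)*(n_G/L)*L and yields the
familiar 0-1.5 scale.

The number of modes is estimated by fitting univariate Gaussian mixtures
(equal-variance and free-variance families, k = 1..k_max) by EM and
choosing the fit with the best BIC, using the model-based-clustering
convention BIC = 2*logL - p*ln(n), selected by MAXIMUM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numba
import numpy as np
import pandas as pd

from .io import SequenceSet

__all__ = [
    "NucleotideCounts",
    "CpGTable",
    "MixtureFit",
    "MixtureSelection",
    "count_nucleotides",
    "cpg_oe",
    "cpg_table",
    "fit_mixture",
    "select_components",
]

_SD_FLOOR = 1e-4  # variance floor 1e-8


@dataclass
class NucleotideCounts:
    """Unambiguous nucleotide and CpG-dinucleotide counts for one sequence."""

    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_CpG: int

    @property
    def length(self) -> int:
        """Number of unambiguous bases (A+C+G+T)."""
        return self.n_A + self.n_C + self.n_G + self.n_T


def count_nucleotides(sequence: str) -> NucleotideCounts:
    """Case-insensitive A/C/G/T and CpG counts.

    Ambiguity codes and N are excluded from all counts; a CpG is counted
    only when C and G are physically adjacent in the input, so an
    intervening ambiguous base breaks the dinucleotide.
    """
    up = sequence.upper()
    return NucleotideCounts(
        n_A=up.count("A"),
        n_C=up.count("C"),
        n_G=up.count("G"),
        n_T=up.count("T"),
        n_CpG=up.count("CG"),
    )


def cpg_oe(
    counts: NucleotideCounts,
    normalization: str = "length_normalized",
) -> Optional[float]:
    """CpG observed/expected ratio; None when undefined
    (no C, no G, or fewer than two unambiguous bases)."""
    if normalization not in ("literal", "length_normalized"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if counts.n_C == 0 or counts.n_G == 0 or counts.length < 2:
        return None
    oe = counts.n_CpG / (counts.n_C * counts.n_G)
    if normalization == "length_normalized":
        oe *= counts.length
    return oe


@dataclass
class CpGTable:
    """Per-gene nucleotide counts and CpG[o/e] values."""

    rows: pd.DataFrame  # index gene_id; columns n_A..n_T, n_CpG, length, cpg_oe
    normalization: str

    def defined_values(self) -> np.ndarray:
        """CpG[o/e] values with undefined rows excluded."""
        return self.rows["cpg_oe"].dropna().to_numpy()

    def histogram(self, bin_width: float = 0.05) -> pd.DataFrame:
        """Binned counts covering [0, max] with the given bin width."""
        vals = self.defined_values()
        if len(vals) == 0:
            raise ValueError("no defined CpG[o/e] values to histogram")
        edges = np.arange(0, vals.max() + bin_width, bin_width)
        if edges[-1] < vals.max() or len(edges) < 2:
            edges = np.append(edges, edges[-1] + bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index_label="gene_id")


def cpg_table(
    genes: SequenceSet,
    normalization: str = "length_normalized",
) -> CpGTable:
    """One row per gene; genes with undefined CpG[o/e] are retained with NaN."""
    if len(genes) == 0:
        raise ValueError("empty gene sequence set")
    rows = []
    for gid, seq in genes:
        c = count_nucleotides(seq)
        rows.append(
            {
                "gene_id": gid,
                "n_A": c.n_A,
                "n_C": c.n_C,
                "n_G": c.n_G,
                "n_T": c.n_T,
                "n_CpG": c.n_CpG,
                "length": c.length,
                "cpg_oe": cpg_oe(c, normalization),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return CpGTable(rows=df, normalization=normalization)


# ---------------------------------------------------------------------------
# Univariate Gaussian mixtures


@dataclass
class MixtureFit:
    """One fitted univariate Gaussian mixture."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    family: str
    log_likelihood: float
    bic: float
    n: int
    converged: bool
    seed: int
    n_iter: int = 0
    loglik_trajectory: np.ndarray = field(default=None, repr=False)

    @property
    def n_parameters(self) -> int:
        # weights contribute k-1, means k, variances k (free) or 1 (equal)
        if self.family == "equal_variance":
            return 2 * self.k
        return 3 * self.k - 1


@numba.njit(cache=False)
def _em_kernel(x, w, mu, sd, equal_variance, max_iter, tol, sd_floor):
    """EM for one restart; mutates w/mu/sd in place.

    Returns (status, trajectory, n_iter) with status 1 = converged,
    0 = max_iter reached, -1 = collapsed (empty component or variance
    pinned at the floor).  The log-likelihood trajectory is evaluated at
    the parameters entering each iteration, so it is non-decreasing.
    """
    n = x.shape[0]
    k = mu.shape[0]
    log_c = -0.5 * math.log(2.0 * math.pi)
    var_floor = sd_floor * sd_floor
    r = np.empty((n, k))
    lw = np.empty(k)
    lsd = np.empty(k)
    traj = np.empty(max_iter)
    prev_ll = -np.inf
    status = 0
    n_iter = 0
    for it in range(max_iter):
        # E-step with a per-point logsumexp
        for j in range(k):
            lw[j] = math.log(w[j])
            lsd[j] = math.log(sd[j])
        ll = 0.0
        for i in range(n):
            m = -1.0e308
            for j in range(k):
                z = (x[i] - mu[j]) / sd[j]
                v = lw[j] - lsd[j] - 0.5 * z * z
                r[i, j] = v
                if v > m:
                    m = v
            s = 0.0
            for j in range(k):
                e = math.exp(r[i, j] - m)
                r[i, j] = e
                s += e
            ll += math.log(s) + m
            inv = 1.0 / s
            for j in range(k):
                r[i, j] *= inv
        ll += n * log_c
        traj[it] = ll
        n_iter = it + 1
        # M-step
        collapsed = False
        sq_total = 0.0
        for j in range(k):
            nk = 0.0
            num = 0.0
            for i in range(n):
                nk += r[i, j]
                num += r[i, j] * x[i]
            if nk < 1e-10:
                collapsed = True
                break
            w[j] = nk / n
            mu[j] = num / nk
            sq = 0.0
            for i in range(n):
                d = x[i] - mu[j]
                sq += r[i, j] * d * d
            if equal_variance:
                sq_total += sq
            else:
                var = sq / nk
                if k > 1 and var < var_floor:
                    collapsed = True
                    break
                sd[j] = math.sqrt(max(var, var_floor))
        if not collapsed and equal_variance:
            var = sq_total / n
            if k > 1 and var < var_floor:
                collapsed = True
            else:
                sv = math.sqrt(max(var, var_floor))
                for j in range(k):
                    sd[j] = sv
        if collapsed:
            status = -1
            break
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            status = 1
            break
        prev_ll = ll
    return status, traj[:n_iter].copy(), n_iter


def _em_restarts(
    x: np.ndarray,
    k: int,
    family: str,
    means0: np.ndarray,  # (R, k) initial means, one row per restart
    sd0: float,
    max_iter: int,
    tol: float,
) -> Optional[tuple]:
    """Run every restart through the EM kernel and keep the best
    non-collapsed one by log-likelihood; None when all collapse."""
    equal = family == "equal_variance"
    best = None
    for row in means0:
        w = np.full(k, 1.0 / k)
        mu = row.copy()
        sd = np.full(k, max(sd0, _SD_FLOOR))
        status, traj, _ = _em_kernel(
            x, w, mu, sd, equal, max_iter, tol, _SD_FLOOR
        )
        if status < 0:
            continue
        ll = float(traj[-1])
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, traj, status == 1)
    return best


def fit_mixture(
    values: Sequence[float],
    k: int,
    family: str = "free_variance",
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    The best of `n_restarts` runs by log-likelihood is returned.  The first
    restart initialises means at the k data quantiles (at (i+0.5)/k);
    later restarts jitter those quantile means with seeded Gaussian noise.
    ``equal_variance`` constrains all component SDs equal (the "E" family
    of model-based clustering); ``free_variance`` is the "V" family.
    BIC = 2*logL - p*ln(n) with p = 2k (equal) or 3k-1 (free); larger is
    better under this convention.
    """
    if family not in ("equal_variance", "free_variance"):
        raise ValueError(f"unknown family {family!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite (exclude undefined upstream)")
    n = len(x)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples (n={n}, k={k})")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance data")

    rng = np.random.default_rng(seed)
    q = np.quantile(x, (np.arange(k) + 0.5) / k)
    data_sd = float(np.std(x))
    sd0 = max(data_sd / max(k, 1), _SD_FLOOR)

    # restart 0 starts at the data quantiles; the rest jitter them
    means0 = np.tile(q, (n_restarts, 1))
    if n_restarts > 1:
        means0[1:] += rng.normal(0, data_sd / 2, size=(n_restarts - 1, k))
    means0.sort(axis=1)
    result = _em_restarts(x, k, family, means0, sd0, max_iter, tol)
    if result is None:
        raise RuntimeError(
            f"all {n_restarts} EM restarts collapsed for k={k} ({family})"
        )
    w, mu, sd, ll, traj, converged = result
    order = np.argsort(mu)
    p = 2 * k if family == "equal_variance" else 3 * k - 1
    return MixtureFit(
        k=k,
        weights=w[order],
        means=mu[order],
        sds=sd[order],
        family=family,
        log_likelihood=ll,
        bic=2.0 * ll - p * math.log(n),
        n=n,
        converged=converged,
        seed=seed,
        n_iter=len(traj),
        loglik_trajectory=traj,
    )


@dataclass
class MixtureSelection:
    """All fits over the (k, family) grid and the BIC-best one."""

    fits: list[MixtureFit]
    selected: MixtureFit
    bic_table: dict[tuple[int, str], float]

    def to_dict(self) -> dict:
        return {
            "selected": {
                "k": self.selected.k,
                "family": self.selected.family,
                "weights": self.selected.weights.tolist(),
                "means": self.selected.means.tolist(),
                "sds": self.selected.sds.tolist(),
                "bic": self.selected.bic,
                "log_likelihood": self.selected.log_likelihood,
                "n": self.selected.n,
            },
            "bic_table": {
                f"{k},{fam}": bic for (k, fam), bic in self.bic_table.items()
            },
        }


def select_components(
    values: Sequence[float],
    k_max: int = 5,
    families: Sequence[str] = ("equal_variance", "free_variance"),
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureSelection:
    """Fit all (k, family) models for k = 1..k_max and select by maximum
    BIC.  Ties (exact BIC equality) prefer smaller k, then equal_variance."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    families = list(families)
    if not families:
        raise ValueError("families must be non-empty")
    master = np.random.default_rng(seed)
    fits: list[MixtureFit] = []
    bic_table: dict[tuple[int, str], float] = {}
    for k in range(1, k_max + 1):
        for family in families:
            sub_seed = int(master.integers(2**31))
            fit = fit_mixture(
                values,
                k,
                family=family,
                n_restarts=n_restarts,
                seed=sub_seed,
                max_iter=max_iter,
                tol=tol,
            )
            fits.append(fit)
            bic_table[(k, family)] = fit.bic
    selected = max(
        fits,
        key=lambda f: (f.bic, -f.k, f.family == "equal_variance"),
    )
    return MixtureSelection(fits=fits, selected=selected, bic_table=bic_table)
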