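"""SNP-based Nei (1972) standard genetic distances across ploidy levels and
principal coordinate analysis with the Lingoes negative-eigenvalue
correction.

Individual-level allele frequencies (dosage / ploidy) make the distance
directly comparable between diploid and tetraploid samples: for a pair of
samples over their pairwise-complete sites,
``J_x = mean_l sum_i x_li^2``, ``J_y`` likewise,
``J_xy = mean_l sum_i x_li y_li``, identity ``I = J_xy / sqrt(J_x J_y)``
and ``D = -ln I`` (capped, since D diverges for allele-disjoint pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import GenotypeMatrix

__all__ = [
    "NeiDistanceMatrix",
    "PCoAResult",
    "sample_allele_frequencies",
    "nei_distance_matrix",
    "pcoa_lingoes",
]

D_CAP_DEFAULT = 10.0
MIN_SHARED_SITES_DEFAULT = 50


@dataclass
class NeiDistanceMatrix:
    labels: list[str]
    D: np.ndarray
    n_shared_sites: np.ndarray
    d_cap: float = D_CAP_DEFAULT
    min_shared_sites: int = MIN_SHARED_SITES_DEFAULT
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def reorder(self, new_labels: list[str]) -> "NeiDistanceMatrix":
        idx = [self.labels.index(l) for l in new_labels]
        return NeiDistanceMatrix(
            labels=list(new_labels),
            D=self.D[np.ix_(idx, idx)],
            n_shared_sites=self.n_shared_sites[np.ix_(idx, idx)],
            d_cap=self.d_cap,
            min_shared_sites=self.min_shared_sites,
            flagged_pairs=list(self.flagged_pairs),
        )


@dataclass
class PCoAResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    lingoes_constant: float
    n_axes_50: int

    def scores_for_variance(self, target: float = 0.5) -> np.ndarray:
        pos = np.clip(self.eigenvalues, 0, None)
        cum = np.cumsum(pos) / pos.sum()
        k = int(np.searchsorted(cum, target) + 1)
        return self.scores[:, :k]


def sample_allele_frequencies(g: GenotypeMatrix, sample: str) -> np.ndarray:
    """Per-site allele-frequency vectors (dosage / ploidy) for one sample.

    Missing sites stay NaN; non-missing vectors sum to 1.
    """
    if sample not in g.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    j = g.index_of(sample)
    return g.dosages[j] / g.ploidy_of[sample]


def _all_frequencies(g: GenotypeMatrix) -> np.ndarray:
    ploidy = g.ploidy_array().astype(float)
    return g.dosages / ploidy[:, None, None]


def nei_distance_matrix(
    g: GenotypeMatrix,
    d_cap: float = D_CAP_DEFAULT,
    min_shared_sites: int = MIN_SHARED_SITES_DEFAULT,
    pool_by_taxon: bool = False,
) -> NeiDistanceMatrix:
    """Nei standard distance between every pair of samples.

    Missing data is handled by pairwise-complete deletion; pairs sharing
    fewer than ``min_shared_sites`` sites are flagged, and pairs sharing no
    sites get D = NaN.  With ``pool_by_taxon=True`` frequencies are first
    averaged within taxa and the matrix is over taxa instead of samples.
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    freqs = _all_frequencies(g)  # (n, L, A)
    if pool_by_taxon:
        taxa = sorted(set(g.taxon_of.values()))
        pooled = []
        for t in taxa:
            idx = [g.index_of(s) for s in g.samples_of_taxon(t)]
            with np.errstate(invalid="ignore"):
                pooled.append(np.nanmean(freqs[idx], axis=0))
        freqs = np.stack(pooled)
        labels = taxa
    else:
        labels = list(g.sample_ids)

    n = freqs.shape[0]
    present = np.isfinite(freqs[:, :, 0])  # (n, L)
    self_j = np.where(present, np.nansum(freqs**2, axis=2), np.nan)  # sum_i x_li^2
    D = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    flagged: list[tuple[str, str]] = []
    for a in range(n):
        shared[a, a] = int(present[a].sum())
        for b in range(a + 1, n):
            both = present[a] & present[b]
            m = int(both.sum())
            shared[a, b] = shared[b, a] = m
            if m == 0:
                D[a, b] = D[b, a] = np.nan
                flagged.append((labels[a], labels[b]))
                continue
            jx = self_j[a, both].mean()
            jy = self_j[b, both].mean()
            jxy = (freqs[a, both] * freqs[b, both]).sum(axis=1).mean()
            identity = jxy / np.sqrt(jx * jy)
            if identity <= np.exp(-d_cap):
                d = d_cap
            else:
                d = -np.log(min(identity, 1.0))
            D[a, b] = D[b, a] = d
            if m < min_shared_sites:
                flagged.append((labels[a], labels[b]))
    return NeiDistanceMatrix(
        labels=labels, D=D, n_shared_sites=shared, d_cap=d_cap,
        min_shared_sites=min_shared_sites, flagged_pairs=flagged,
    )


def pcoa_lingoes(D: np.ndarray, variance_target: float = 0.5) -> PCoAResult:
    """Principal coordinate analysis with the Lingoes correction.

    Double-centres ``-0.5 D^2`` and eigendecomposes; when the smallest
    eigenvalue is materially negative, the constant ``c = |lambda_min|`` is
    added to all squared off-diagonal distances and the decomposition is
    redone, making the configuration Euclidean.  ``n_axes_50`` is the
    smallest axis count whose cumulative eigenvalue share reaches the
    variance target.
    """
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if np.abs(D - D.T).max() > 1e-8:
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]

    def decompose(D2: np.ndarray):
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(D**2)
    c = 0.0
    lam_min = vals.min() if n > 1 else 0.0
    if lam_min < -1e-8:
        c = float(-lam_min)
        D2c = D**2 + 2.0 * c
        np.fill_diagonal(D2c, 0.0)
        vals, vecs = decompose(D2c)
    vals = np.where(np.abs(vals) < 1e-9, 0.0, vals)
    pos = vals > 0
    scores = vecs[:, pos] * np.sqrt(vals[pos])
    total = vals[pos].sum()
    if total <= 0:
        n_axes = 0
        scores = np.zeros((n, 1))
    else:
        cum = np.cumsum(vals[pos]) / total
        n_axes = int(np.searchsorted(cum, variance_target) + 1)
    return PCoAResult(
        scores=scores, eigenvalues=vals, lingoes_constant=c, n_axes_50=n_axes
    )
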