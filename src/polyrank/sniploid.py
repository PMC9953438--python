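"""Per-SNP five-category classification of (diploid parent, diploid parent,
tetraploid child) triplets, and genome-wide parentage scans.

For a site where both parents are homozygous (fixed for single alleles a
and b), the child's genotype falls into:

* category 1 / 2 — inter-specific SNPs: parents differ and the child is
  fixed for parent 1's (CAT1) or parent 2's (CAT2) allele;
* categories 3+4 — derived SNPs: the child carries an allele absent from
  both parents (not separable without phasing, reported jointly as CAT34);
* category 5 — homeo-SNPs: parents differ and the child combines exactly
  the two parental alleles, the signature of recent allopolyploidy.

Sites with missing calls or a heterozygous parent are unclassified.  A
recent allotetraploid is expected to be rich in CAT5 with respect to its
true parent pair, so the scan ranks candidate parent pairs by mean CAT5
proportion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .formats_io import GenotypeMatrix

__all__ = ["SnpCategory", "TripletProfile", "categorize_snp", "triplet_profile", "parent_scan"]


class SnpCategory(Enum):
    CAT1 = "cat1"
    CAT2 = "cat2"
    CAT34 = "cat34"
    CAT5 = "cat5"
    UNCLASSIFIED = "unclassified"


CATEGORIES = (SnpCategory.CAT1, SnpCategory.CAT2, SnpCategory.CAT34, SnpCategory.CAT5)


@dataclass
class TripletProfile:
    parent1: str
    parent2: str
    child: str
    per_individual: pd.DataFrame  # rows: child individuals; cols: cat proportions + n
    mean_proportions: dict[str, float]
    n_sites: int

    @property
    def mean_cat5(self) -> float:
        return self.mean_proportions["cat5"]


def _fixed_allele(dosage: np.ndarray, ploidy: int) -> int | None:
    """Index of the single allele a homozygous call is fixed for, else None."""
    nz = np.nonzero(dosage > 0)[0]
    if len(nz) != 1:
        return None
    if int(round(dosage[nz[0]])) != ploidy:
        return None
    return int(nz[0])


def categorize_snp(
    p1_dosage: np.ndarray,
    p2_dosage: np.ndarray,
    child_dosage: np.ndarray,
    ploidies: tuple[int, int, int] = (2, 2, 4),
) -> SnpCategory:
    """Classify one site of a parent-parent-child individual triplet."""
    for dos, pl in zip((p1_dosage, p2_dosage, child_dosage), ploidies):
        if np.isfinite(dos[0]) and int(round(np.nansum(dos))) != pl:
            raise ValueError(f"dosage {dos} does not sum to ploidy {pl}")
    if any(not np.isfinite(d[0]) for d in (p1_dosage, p2_dosage, child_dosage)):
        return SnpCategory.UNCLASSIFIED
    a = _fixed_allele(np.asarray(p1_dosage), ploidies[0])
    b = _fixed_allele(np.asarray(p2_dosage), ploidies[1])
    if a is None or b is None:  # heterozygous parent
        return SnpCategory.UNCLASSIFIED
    child_alleles = set(np.nonzero(np.asarray(child_dosage) > 0)[0].tolist())
    if not child_alleles <= {a, b}:
        # novel allele in the child; jointly CAT3/CAT4 (indistinguishable
        # unphased); extended to diverged parents for exhaustiveness
        return SnpCategory.CAT34
    if a == b:
        return SnpCategory.UNCLASSIFIED  # monomorphic across the triplet
    if child_alleles == {a}:
        return SnpCategory.CAT1
    if child_alleles == {b}:
        return SnpCategory.CAT2
    return SnpCategory.CAT5  # both parental alleles combined: homeo-SNP


def categorize_sites(
    p1: np.ndarray, p2: np.ndarray, child: np.ndarray,
    ploidies: tuple[int, int, int],
) -> np.ndarray:
    """Vectorised site classification: integer codes, -1 = unclassified,
    0..3 = CAT1, CAT2, CAT34, CAT5.  Inputs are (L, A) dosage arrays."""
    L = p1.shape[0]
    codes = np.full(L, -1, dtype=np.int8)
    ok = np.isfinite(p1[:, 0]) & np.isfinite(p2[:, 0]) & np.isfinite(child[:, 0])
    p1f = np.where(np.isfinite(p1), p1, -1.0).max(axis=1) == ploidies[0]
    p2f = np.where(np.isfinite(p2), p2, -1.0).max(axis=1) == ploidies[1]
    usable = ok & p1f & p2f
    if not usable.any():
        return codes
    a = np.argmax(p1, axis=1)
    b = np.argmax(p2, axis=1)
    carries = child > 0
    arange = np.arange(L)
    carr_a = carries[arange, a]
    carr_b = carries[arange, b]
    n_carried = carries.sum(axis=1)
    n_ab = carr_a.astype(int) + np.where(a != b, carr_b, 0)
    novel = n_carried > n_ab
    codes[usable & novel] = 2  # CAT34
    diff = usable & ~novel & (a != b)
    codes[diff & carr_a & ~carr_b] = 0  # CAT1
    codes[diff & ~carr_a & carr_b] = 1  # CAT2
    codes[diff & carr_a & carr_b] = 3  # CAT5
    return codes


def triplet_profile(
    g: GenotypeMatrix,
    parent1_samples: list[str],
    parent2_samples: list[str],
    child_samples: list[str],
    parent1_label: str = "parent1",
    parent2_label: str = "parent2",
    child_label: str = "child",
) -> TripletProfile:
    """Classify every (p1, p2, child) individual combination at every site
    and aggregate per-child-individual category proportions (over classified
    sites), then average arithmetically across child individuals."""
    sets = [set(parent1_samples), set(parent2_samples), set(child_samples)]
    if any(not s for s in sets):
        raise ValueError("every sample group must be non-empty")
    if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
        raise ValueError("parent/child sample sets must be disjoint")

    ploidy = g.ploidy_of
    rows = []
    for child in child_samples:
        counts = {c.value: 0 for c in CATEGORIES}
        jc = g.index_of(child)
        for p1, p2 in itertools.product(parent1_samples, parent2_samples):
            j1, j2 = g.index_of(p1), g.index_of(p2)
            pls = (ploidy[p1], ploidy[p2], ploidy[child])
            codes = categorize_sites(
                g.dosages[j1], g.dosages[j2], g.dosages[jc], pls
            )
            for code, cat in enumerate(CATEGORIES):
                counts[cat.value] += int((codes == code).sum())
        total = sum(counts.values())
        row = {"individual": child, "n_classified": total}
        for c in CATEGORIES:
            row[c.value] = counts[c.value] / total if total else np.nan
        rows.append(row)
    per_ind = pd.DataFrame(rows).set_index("individual")
    means = {c.value: float(per_ind[c.value].mean()) for c in CATEGORIES}
    return TripletProfile(
        parent1=parent1_label, parent2=parent2_label, child=child_label,
        per_individual=per_ind, mean_proportions=means, n_sites=g.n_sites,
    )


def parent_scan(
    g: GenotypeMatrix,
    candidate_parent_taxa: list[str],
    child_taxon: str,
) -> pd.DataFrame:
    """Evaluate every unordered candidate parent-taxon pair for one child
    taxon; rows sorted by mean homeo-SNP (CAT5) proportion, descending."""
    if len(candidate_parent_taxa) < 2:
        raise ValueError("need >= 2 candidate parent taxa")
    if child_taxon in candidate_parent_taxa:
        raise ValueError("child taxon cannot be among candidate parents")
    child_samples = g.samples_of_taxon(child_taxon)
    rows = []
    for ta, tb in itertools.combinations(candidate_parent_taxa, 2):
        prof = triplet_profile(
            g,
            g.samples_of_taxon(ta),
            g.samples_of_taxon(tb),
            child_samples,
            parent1_label=ta, parent2_label=tb, child_label=child_taxon,
        )
        rows.append({
            "parent1": ta, "parent2": tb, "child": child_taxon,
            **prof.mean_proportions,
            "n_sites": prof.n_sites,
        })
    df = pd.DataFrame(rows).sort_values("cat5", ascending=False, ignore_index=True)
    return df
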