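"""Published pairwise test results for the eight tetraploid marguerite
(ox-eye daisy) morphotaxa, used as regression fixtures for the evidence
matrix and rank-decision engine.

Values are Bonferroni-corrected p-values truncated to 1.0; entries printed
as "<0.01" are encoded 0.0 (they only ever enter alpha = 0.01 threshold
comparisons), and "n/a" (the single-raster-cell point endemic, for which
niche and range modelling is impossible) is None.
"""

from __future__ import annotations

TAXA = [
    "cantabricum",
    "crassifolium",
    "delarbrei",
    "ruscinonense",
    "ircutianum",
    "leucolepis",
    "meridionale",
    "pseudosylvaticum",
]

S = 0.0  # printed as "<0.01"


def _sym(d: dict) -> dict:
    out = {}
    for (a, b), v in d.items():
        out[frozenset((a, b))] = v
    return out


# Welch's test on leaf dissection indices (upper triangle of the published
# morphology table)
LDI_P = _sym({
    ("cantabricum", "crassifolium"): S,
    ("cantabricum", "delarbrei"): 0.21,
    ("cantabricum", "ruscinonense"): S,
    ("cantabricum", "ircutianum"): S,
    ("cantabricum", "leucolepis"): S,
    ("cantabricum", "meridionale"): S,
    ("cantabricum", "pseudosylvaticum"): S,
    ("crassifolium", "delarbrei"): S,
    ("crassifolium", "ruscinonense"): S,
    ("crassifolium", "ircutianum"): S,
    ("crassifolium", "leucolepis"): S,
    ("crassifolium", "meridionale"): S,
    ("crassifolium", "pseudosylvaticum"): S,
    ("delarbrei", "ruscinonense"): S,
    ("delarbrei", "ircutianum"): S,
    ("delarbrei", "leucolepis"): S,
    ("delarbrei", "meridionale"): 1.0,
    ("delarbrei", "pseudosylvaticum"): S,
    ("ruscinonense", "ircutianum"): S,
    ("ruscinonense", "leucolepis"): S,
    ("ruscinonense", "meridionale"): S,
    ("ruscinonense", "pseudosylvaticum"): S,
    ("ircutianum", "leucolepis"): 1.0,
    ("ircutianum", "meridionale"): S,
    ("ircutianum", "pseudosylvaticum"): S,
    ("leucolepis", "meridionale"): S,
    ("leucolepis", "pseudosylvaticum"): S,
    ("meridionale", "pseudosylvaticum"): S,
})

# permutation test on Euclidean distances in shape-PC space (lower
# triangle, left value)
PERM_P = _sym({
    ("crassifolium", "cantabricum"): 1.0,
    ("delarbrei", "cantabricum"): 1.0,
    ("delarbrei", "crassifolium"): 0.44,
    ("ruscinonense", "cantabricum"): 0.04,
    ("ruscinonense", "crassifolium"): 0.02,
    ("ruscinonense", "delarbrei"): 1.0,
    ("ircutianum", "cantabricum"): S,
    ("ircutianum", "crassifolium"): 0.17,
    ("ircutianum", "delarbrei"): 0.02,
    ("ircutianum", "ruscinonense"): S,
    ("leucolepis", "cantabricum"): S,
    ("leucolepis", "crassifolium"): S,
    ("leucolepis", "delarbrei"): S,
    ("leucolepis", "ruscinonense"): S,
    ("leucolepis", "ircutianum"): 1.0,
    ("meridionale", "cantabricum"): 1.0,
    ("meridionale", "crassifolium"): 1.0,
    ("meridionale", "delarbrei"): 1.0,
    ("meridionale", "ruscinonense"): 1.0,
    ("meridionale", "ircutianum"): 1.0,
    ("meridionale", "leucolepis"): 0.38,
    ("pseudosylvaticum", "cantabricum"): S,
    ("pseudosylvaticum", "crassifolium"): S,
    ("pseudosylvaticum", "delarbrei"): 0.06,
    ("pseudosylvaticum", "ruscinonense"): 0.01,
    ("pseudosylvaticum", "ircutianum"): S,
    ("pseudosylvaticum", "leucolepis"): S,
    ("pseudosylvaticum", "meridionale"): 1.0,
})

# distance-based non-parametric MANOVA (lower triangle, right value)
NPMANOVA_P = _sym({
    ("crassifolium", "cantabricum"): 1.0,
    ("delarbrei", "cantabricum"): 1.0,
    ("delarbrei", "crassifolium"): 1.0,
    ("ruscinonense", "cantabricum"): S,
    ("ruscinonense", "crassifolium"): S,
    ("ruscinonense", "delarbrei"): 1.0,
    ("ircutianum", "cantabricum"): S,
    ("ircutianum", "crassifolium"): S,
    ("ircutianum", "delarbrei"): 0.83,
    ("ircutianum", "ruscinonense"): S,
    ("leucolepis", "cantabricum"): S,
    ("leucolepis", "crassifolium"): S,
    ("leucolepis", "delarbrei"): S,
    ("leucolepis", "ruscinonense"): S,
    ("leucolepis", "ircutianum"): S,
    ("meridionale", "cantabricum"): 1.0,
    ("meridionale", "crassifolium"): 1.0,
    ("meridionale", "delarbrei"): 0.83,
    ("meridionale", "ruscinonense"): 1.0,
    ("meridionale", "ircutianum"): S,
    ("meridionale", "leucolepis"): S,
    ("pseudosylvaticum", "cantabricum"): S,
    ("pseudosylvaticum", "crassifolium"): S,
    ("pseudosylvaticum", "delarbrei"): S,
    ("pseudosylvaticum", "ruscinonense"): S,
    ("pseudosylvaticum", "ircutianum"): S,
    ("pseudosylvaticum", "leucolepis"): S,
    ("pseudosylvaticum", "meridionale"): 1.0,
})

# niche-equivalency tests: Schoener's D (upper) and Warren's I (lower);
# the point endemic is untestable
_NA = [("meridionale", t) for t in TAXA if t != "meridionale"]
NICHE_D_P = _sym({
    ("cantabricum", "crassifolium"): 0.52,
    ("cantabricum", "delarbrei"): 0.0,
    ("cantabricum", "ruscinonense"): 0.32,
    ("cantabricum", "ircutianum"): 0.0,
    ("cantabricum", "leucolepis"): 0.0,
    ("cantabricum", "pseudosylvaticum"): 0.0,
    ("crassifolium", "delarbrei"): 0.0,
    ("crassifolium", "ruscinonense"): 0.0,
    ("crassifolium", "ircutianum"): 0.0,
    ("crassifolium", "leucolepis"): 0.0,
    ("crassifolium", "pseudosylvaticum"): 0.0,
    ("delarbrei", "ruscinonense"): 0.0,
    ("delarbrei", "ircutianum"): 0.0,
    ("delarbrei", "leucolepis"): 0.0,
    ("delarbrei", "pseudosylvaticum"): 0.0,
    ("ruscinonense", "ircutianum"): 0.0,
    ("ruscinonense", "leucolepis"): 0.0,
    ("ruscinonense", "pseudosylvaticum"): 0.0,
    ("ircutianum", "leucolepis"): 0.0,
    ("ircutianum", "pseudosylvaticum"): 0.0,
    ("leucolepis", "pseudosylvaticum"): 0.0,
    **{pair: None for pair in _NA},
})
NICHE_I_P = _sym({
    ("crassifolium", "cantabricum"): 0.31,
    ("delarbrei", "cantabricum"): 0.0,
    ("ruscinonense", "cantabricum"): 0.52,
    ("ruscinonense", "crassifolium"): 0.0,
    ("ruscinonense", "delarbrei"): 0.0,
    ("ircutianum", "cantabricum"): 0.0,
    ("ircutianum", "crassifolium"): 0.0,
    ("ircutianum", "delarbrei"): 0.0,
    ("ircutianum", "ruscinonense"): 0.0,
    ("leucolepis", "cantabricum"): 0.0,
    ("leucolepis", "crassifolium"): 0.0,
    ("leucolepis", "delarbrei"): 0.0,
    ("leucolepis", "ruscinonense"): 0.0,
    ("leucolepis", "ircutianum"): 0.0,
    ("pseudosylvaticum", "cantabricum"): 0.0,
    ("pseudosylvaticum", "crassifolium"): 0.0,
    ("pseudosylvaticum", "delarbrei"): 0.0,
    ("pseudosylvaticum", "ruscinonense"): 0.0,
    ("pseudosylvaticum", "ircutianum"): 0.0,
    ("pseudosylvaticum", "leucolepis"): 0.0,
    ("crassifolium", "delarbrei"): 0.0,
    **{pair: None for pair in _NA},
})

# pairwise sympatry permutation tests (significant = allopatry)
SYMPATRY_P = _sym({
    ("cantabricum", "crassifolium"): 1.0,
    ("cantabricum", "delarbrei"): 0.0,
    ("cantabricum", "ruscinonense"): 0.0,
    ("cantabricum", "ircutianum"): 0.0,
    ("cantabricum", "leucolepis"): 0.0,
    ("cantabricum", "pseudosylvaticum"): 0.0,
    ("crassifolium", "delarbrei"): 0.0,
    ("crassifolium", "ruscinonense"): 0.0,
    ("crassifolium", "ircutianum"): 0.0,
    ("crassifolium", "leucolepis"): 0.0,
    ("crassifolium", "pseudosylvaticum"): 0.0,
    ("delarbrei", "ruscinonense"): 0.0,
    ("delarbrei", "ircutianum"): 0.0,
    ("delarbrei", "leucolepis"): 0.0,
    ("delarbrei", "pseudosylvaticum"): 0.0,
    ("ruscinonense", "ircutianum"): 0.05,
    ("ruscinonense", "leucolepis"): 0.0,
    ("ruscinonense", "pseudosylvaticum"): 0.0,
    ("ircutianum", "leucolepis"): 0.0,
    ("ircutianum", "pseudosylvaticum"): 0.0,
    ("leucolepis", "pseudosylvaticum"): 0.0,
    **{pair: None for pair in _NA},
})

# consensus clusters at the BIC-optimal k = 6: the widespread taxon merges
# with the Cantabrian one, and the two Massif Central endemics merge
CLUSTER_AT_K6 = {
    "cantabricum": 0,
    "ircutianum": 0,
    "delarbrei": 1,
    "meridionale": 1,
    "crassifolium": 2,
    "ruscinonense": 3,
    "leucolepis": 4,
    "pseudosylvaticum": 5,
}

# documented judgement calls entered as explicit overrides
OVERRIDES = {
    frozenset(("delarbrei", "meridionale")): {"edaphic_distinct"},
    frozenset(("ircutianum", "leucolepis")): {"hybrid_swarms"},
}

MORPHO_P = {
    key: (LDI_P[key], PERM_P[key], NPMANOVA_P[key])
    for key in LDI_P
}
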