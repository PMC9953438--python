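"""Four-axis evidence integration and species-rank recommendations.

Per unordered taxon pair, significance flags are collected on four axes —
genetic (distinct consensus clusters at the BIC-optimal k), geographic
(significant sympatry test = allopatry), ecological (niche-equivalency on
Schoener's D and Warren's I), and morphological (Welch on LDI, permutation
shape test, NPMANOVA) — and fed to an ordered, explicit rule list that
recommends "distinct species", "subspecies of one species", or
"conspecific".  Judgement calls the data cannot encode (known hybrid
swarms, edaphic niche differences invisible to climate layers) enter as
named per-pair overrides, never as hidden heuristics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Flag",
    "EvidenceMatrix",
    "RankDecision",
    "build_evidence_matrix",
    "rank_decisions",
    "species_arrangement",
    "AXES",
    "KNOWN_OVERRIDES",
]

AXES = ("GEN", "GEO", "EcoD", "EcoI", "ML", "MP", "MN")
ECO_AXES = ("EcoD", "EcoI")
MORPH_AXES = ("ML", "MP", "MN")
KNOWN_OVERRIDES = {"hybrid_swarms", "edaphic_distinct"}


class Flag(Enum):
    SIGNIFICANT = "significant"
    NON_SIGNIFICANT = "non-significant"
    NOT_TESTABLE = "not-testable"


@dataclass
class EvidenceMatrix:
    taxa: list[str]
    flags: dict[frozenset, dict[str, Flag]]  # pair -> axis -> flag
    alpha: float = 0.01

    def pair(self, a: str, b: str) -> dict[str, Flag]:
        return self.flags[frozenset((a, b))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(self.taxa, 2):
            row = {"taxon_a": a, "taxon_b": b}
            row.update({ax: fl.value for ax, fl in self.pair(a, b).items()})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class RankDecision:
    pair: tuple[str, str]
    recommendation: str  # distinct species | subspecies of one species | conspecific
    rule_id: str
    rationale: str


def _flag_from_p(p: float | None, alpha: float) -> Flag:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return Flag.NOT_TESTABLE
    return Flag.SIGNIFICANT if p < alpha else Flag.NON_SIGNIFICANT


def build_evidence_matrix(
    cluster_labels: dict[str, int],
    sympatry_p: dict[frozenset, float | None],
    niche_p: dict[frozenset, tuple[float | None, float | None]],
    morpho_p: dict[frozenset, tuple[float, float, float]],
    alpha: float = 0.01,
) -> EvidenceMatrix:
    """Assemble per-pair axis flags from Bonferroni-corrected p-values.

    ``cluster_labels`` maps taxon -> consensus cluster at the BIC-optimal
    k; GEN is significant iff the two taxa occupy different clusters.
    ``niche_p`` holds (p_D, p_I); ``morpho_p`` holds (p_LDI, p_perm,
    p_npmanova); None/NaN means not testable (the single-cell taxon case).
    """
    taxa = sorted(cluster_labels)
    for table, name in ((sympatry_p, "sympatry"), (niche_p, "niche"), (morpho_p, "morphology")):
        for key in table:
            if not key <= set(taxa):
                raise ValueError(f"{name} table mentions unknown taxa {set(key) - set(taxa)}")
    flags: dict[frozenset, dict[str, Flag]] = {}
    for a, b in itertools.combinations(taxa, 2):
        key = frozenset((a, b))
        gen = (
            Flag.SIGNIFICANT
            if cluster_labels[a] != cluster_labels[b]
            else Flag.NON_SIGNIFICANT
        )
        geo = _flag_from_p(sympatry_p.get(key), alpha)
        p_d, p_i = niche_p.get(key, (None, None))
        if key not in morpho_p:
            raise ValueError(f"morphology table missing pair {tuple(sorted(key))}")
        p_ldi, p_perm, p_np = morpho_p[key]
        flags[key] = {
            "GEN": gen,
            "GEO": geo,
            "EcoD": _flag_from_p(p_d, alpha),
            "EcoI": _flag_from_p(p_i, alpha),
            "ML": _flag_from_p(p_ldi, alpha),
            "MP": _flag_from_p(p_perm, alpha),
            "MN": _flag_from_p(p_np, alpha),
        }
    return EvidenceMatrix(taxa=taxa, flags=flags, alpha=alpha)


# ---------------------------------------------------------------------------
# rule engine
# ---------------------------------------------------------------------------

def _any_sig(flags: dict[str, Flag], axes) -> bool:
    return any(flags[a] is Flag.SIGNIFICANT for a in axes)


def _geo_allopatric(flags: dict[str, Flag]) -> bool:
    # a significant sympatry test means allopatry; an untestable point
    # endemic is treated as allopatric-by-endemicity
    return flags["GEO"] in (Flag.SIGNIFICANT, Flag.NOT_TESTABLE)


def rank_decisions(
    evidence: EvidenceMatrix,
    overrides: dict[frozenset, set[str]] | None = None,
) -> list[RankDecision]:
    """Apply the ordered default ruleset to every pair.

    R-hybrid: genetically distinct but documented hybrid swarms in contact
    zones -> keep at subspecific rank for conservative reasons (this
    override dominates the species rule).  R1: genetic distinctness plus
    any ecological or morphological significance -> distinct species.
    R2: no genetic differentiation but allopatry (or untestable endemicity)
    plus ecological/morphological signal or a declared edaphic difference
    -> subspecies.  R3: all axes non-significant -> conspecific.
    R-default: remaining combinations -> subspecies (conservative).
    """
    overrides = overrides or {}
    for key, names in overrides.items():
        unknown = set(names) - KNOWN_OVERRIDES
        if unknown:
            raise ValueError(f"unknown override keys {sorted(unknown)} for pair {tuple(key)}")
    out: list[RankDecision] = []
    for a, b in itertools.combinations(evidence.taxa, 2):
        key = frozenset((a, b))
        fl = evidence.pair(a, b)
        ov = overrides.get(key, set())
        eco = _any_sig(fl, ECO_AXES)
        morph = _any_sig(fl, MORPH_AXES)
        gen_sig = fl["GEN"] is Flag.SIGNIFICANT

        if gen_sig and "hybrid_swarms" in ov:
            dec = RankDecision(
                (a, b), "subspecies of one species", "R-hybrid",
                "genetically distinct, but documented hybrid swarms in zones of "
                "contact argue for conservative subspecific ranking",
            )
        elif gen_sig and (eco or morph):
            dec = RankDecision(
                (a, b), "distinct species", "R1",
                "genetically distinct with corroborating ecological and/or "
                "morphological differentiation",
            )
        elif (not gen_sig) and _geo_allopatric(fl) and (eco or morph or "edaphic_distinct" in ov):
            why = "ecological/morphological signal" if (eco or morph) else \
                "declared edaphic niche difference"
            dec = RankDecision(
                (a, b), "subspecies of one species", "R2",
                f"insufficient genetic differentiation; allopatric with {why}",
            )
        elif not gen_sig and not eco and not morph and fl["GEO"] is Flag.NON_SIGNIFICANT:
            dec = RankDecision(
                (a, b), "conspecific", "R3",
                "no axis shows significant differentiation",
            )
        elif gen_sig:
            dec = RankDecision(
                (a, b), "distinct species", "R-gen",
                "genetic differentiation alone (no corroborating axis testable "
                "or significant)",
            )
        else:
            dec = RankDecision(
                (a, b), "conspecific", "R-default",
                "no genetic differentiation and no allopatry signal",
            )
        out.append(dec)
    return out


def species_arrangement(decisions: list[RankDecision]) -> list[set[str]]:
    """Merge pairs not recommended as distinct species into species groups
    (transitive closure); returns the resulting species partition."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    taxa: set[str] = set()
    for d in decisions:
        taxa.update(d.pair)
        if d.recommendation != "distinct species":
            ra, rb = find(d.pair[0]), find(d.pair[1])
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for t in sorted(taxa):
        groups.setdefault(find(t), set()).add(t)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])


def decisions_to_frame(decisions: list[RankDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon_a": d.pair[0], "taxon_b": d.pair[1],
                "recommendation": d.recommendation,
                "rule": d.rule_id, "rationale": d.rationale,
            }
            for d in decisions
        ]
    )
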