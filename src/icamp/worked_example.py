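"""Synthetic worked-example inputs for the signature and concordance rules.

The reference analysis this package reimplements applied two small
deterministic rules to per-gene tables that are not redistributable here: a fold-change
exclusion over 7 cancer types ("exclude genes with FC < 2 in five or more
cancer types"), which reduced the immune-annotated candidates to a 44
up / 52 down signature, and an ovarian-validation labeling rule over 6
external datasets, under which 33 of the 44 up genes were elevated, 3
repressed and 8 undetermined, while of the 52 down genes 28 were
repressed, 7 unchanged, 10 elevated and 7 undetermined — at least 61 of
96 genes concordant.

The per-gene tables themselves are not printed in the main text, so the
objects built here are SYNTHETIC stand-ins: deterministic per-gene fold
changes and evidence counts constructed to be consistent with those
published marginal totals.  Applying the package's actual rules to them
must reproduce the totals — which is what the worked-example tests and
the acceptance script do; the rules are additionally verified against
exhaustive truth tables independent of these stand-ins.
"""

from __future__ import annotations

from .concordance import DirectionEvidence
from .signature import SignatureGene

N_UP = 44
N_DOWN = 52

# per-direction validation outcome mix consistent with the published totals:
# up: 33 elevated, 3 repressed, 8 undetermined (no up gene was "unchanged")
# down: 28 repressed, 10 elevated, 7 unchanged, 7 undetermined
_UP_OUTCOMES = [("elevated", 33), ("repressed", 3), ("undetermined", 8)]
_DOWN_OUTCOMES = [
    ("repressed", 28),
    ("elevated", 10),
    ("unchanged", 7),
    ("undetermined", 7),
]

# evidence-count patterns that produce each label under the labeling rule;
# cycled through for variety (all with n_tested = 6 validation datasets)
_PATTERNS = {
    "elevated": [(2, 0), (1, 0), (4, 0), (3, 1), (5, 0)],
    "repressed": [(0, 2), (0, 1), (0, 4), (1, 3), (0, 5)],
    "unchanged": [(0, 0)],
    "undetermined": [(2, 2), (1, 1), (2, 1), (1, 2)],
}


def synthetic_ovarian_evidence() -> tuple[list[DirectionEvidence], dict[str, str]]:
    """Synthetic per-gene validation evidence with known signature directions.

    Returns (evidence list, gene -> signature direction).  The evidence
    counts are a deterministic stand-in constructed so the labeling rule
    reproduces the published per-direction label totals.
    """
    evidence: list[DirectionEvidence] = []
    directions: dict[str, str] = {}
    idx = 0
    for direction, outcomes in (("up", _UP_OUTCOMES), ("down", _DOWN_OUTCOMES)):
        for outcome, count in outcomes:
            for k in range(count):
                gene = f"SYN{idx:03d}"
                idx += 1
                n_up, n_down = _PATTERNS[outcome][k % len(_PATTERNS[outcome])]
                evidence.append(
                    DirectionEvidence(gene=gene, n_up=n_up, n_down=n_down,
                                      n_tested=6)
                )
                directions[gene] = direction
    return evidence, directions


# deterministic per-study FC patterns: number of the 7 studies with FC >= 2
# (the retained genes had FC >= 2 in 3-7 cancer types)
_RETAINED_N_HIGH = [3, 4, 5, 6, 7]
_EXCLUDED_N_HIGH = [0, 1, 2]
N_EXCLUDED = 24  # immune candidates removed by the fold-change rule

_STUDIES = [f"cancer_type_{i+1}" for i in range(7)]


def _fc_pattern(n_high: int, rank: int) -> dict[str, float]:
    """Per-study directional fold changes with ``n_high`` studies >= 2."""
    high = 2.0 + 0.25 * (rank % 5)          # 2.0 .. 3.0, boundary included
    low = 1.2 + 0.15 * (rank % 4)           # 1.2 .. 1.65, always < 2
    return {
        s: (high if j < n_high else low) for j, s in enumerate(_STUDIES)
    }


def synthetic_signature_candidates() -> list[SignatureGene]:
    """Synthetic immune candidate genes for the fold-change exclusion rule.

    120 immune-annotated candidates (44 up and 52 down with FC >= 2 in
    3-7 of the 7 studies, plus 24 with FC >= 2 in at most 2 studies) —
    a deterministic stand-in such that applying the exclusion rule leaves
    the published 44 up / 52 down signature split.
    """
    out: list[SignatureGene] = []
    idx = 0
    for direction, n_kept in (("up", N_UP), ("down", N_DOWN)):
        for k in range(n_kept):
            out.append(SignatureGene(
                gene=f"SYN{idx:03d}", direction=direction,
                fc_per_study=_fc_pattern(_RETAINED_N_HIGH[k % 5], k),
                immune=True))
            idx += 1
    for k in range(N_EXCLUDED):
        direction = "up" if k % 2 == 0 else "down"
        out.append(SignatureGene(
            gene=f"SYNX{k:03d}", direction=direction,
            fc_per_study=_fc_pattern(_EXCLUDED_N_HIGH[k % 3], k),
            immune=True))
    return out
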