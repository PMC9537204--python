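"""Rule-based classification of Camelina seed protein profiles.

Implements two fixed decision schemes over quantified peak tables:

* species assignment for the nine Camelina taxa, from the presence or
  absence of discriminating peaks (17, 14, 33, 12, 29 kDa under reducing
  conditions; 54 kDa under non-reducing conditions);
* assignment of C. sativa samples to the three major non-reducing
  seed-protein profiles (single ~51 kDa peak with a higher-MW shoulder;
  ~23 kDa marker with a broad ~52/55 doublet; two large ~51/54 peaks).

Samples that satisfy no rule are reported as unassigned with a reason,
never forced to the nearest leaf.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .electropherogram import (
    MATCH_TOL_KDA,
    PeakTable,
    Trace,
    detect_shoulder,
    match_peak,
    quantify_trace,
)


@dataclasses.dataclass(frozen=True)
class DecisionRule:
    """One presence/absence test on a nominal peak, with two branches.

    Branches are either further rules or leaf labels, so a rule is the
    root of a finite binary decision tree.
    """

    condition: str               # "reduced" | "nonreduced"
    nominal_kda: float
    tol_kda: float
    present: Union["DecisionRule", str]
    absent: Union["DecisionRule", str]

    def describe(self) -> str:
        return f"{self.nominal_kda:g} kDa ({self.condition})"


@dataclasses.dataclass
class ClassificationResult:
    """Leaf label plus the decision path that reached it."""

    label: Optional[str]
    path: list[tuple[str, str]]            # (rule description, outcome)
    unassigned_reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.label is not None


def _rule_to_dict(node: Union[DecisionRule, str]):
    if isinstance(node, str):
        return node
    return {
        "condition": node.condition,
        "nominal_kda": node.nominal_kda,
        "tol_kda": node.tol_kda,
        "present": _rule_to_dict(node.present),
        "absent": _rule_to_dict(node.absent),
    }


def _rule_from_dict(node) -> Union[DecisionRule, str]:
    if isinstance(node, str):
        return node
    return DecisionRule(
        condition=node["condition"],
        nominal_kda=float(node["nominal_kda"]),
        tol_kda=float(node["tol_kda"]),
        present=_rule_from_dict(node["present"]),
        absent=_rule_from_dict(node["absent"]),
    )


def save_rules(tree: DecisionRule, path) -> None:
    """Serialise a rule tree to an editable YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(_rule_to_dict(tree), fh, sort_keys=False)


def load_rules(path) -> DecisionRule:
    with open(path) as fh:
        node = _rule_from_dict(yaml.safe_load(fh))
    if isinstance(node, str):
        raise ValueError("rule config is a bare leaf, not a tree")
    return node


def _rule(condition, nominal, present, absent, tol=MATCH_TOL_KDA):
    return DecisionRule(condition, nominal, tol, present, absent)


#: Labels used at the leaves. Rumelica subspecies and hispida varieties are
#: not separated by the printed scheme and stay as group leaves.
SATIVA = "C. sativa"
MICROCARPA_4X = "C. microcarpa 4X"
MICROCARPA_6X = "C. microcarpa 6X"
RUMELICA_GROUP = "C. rumelica group"
NEGLECTA = "C. neglecta"
LAXA = "C. laxa"
HISPIDA_GROUP = "C. hispida group"

#: The species decision scheme. A 17 kDa reducing peak splits the
#: sativa/microcarpa/rumelica group from neglecta/laxa/hispida; 14 kDa
#: identifies C. sativa; 33 kDa separates the rumelica group from
#: C. microcarpa; a 54 kDa non-reducing peak separates microcarpa 4X from
#: 6X; 12 kDa identifies C. neglecta; 33 + 29 kDa separate C. laxa from
#: the hispida group.
SPECIES_TREE: DecisionRule = _rule(
    "reduced", 17.0,
    present=_rule(
        "reduced", 14.0,
        present=SATIVA,
        absent=_rule(
            "reduced", 33.0,
            present=RUMELICA_GROUP,
            absent=_rule(
                "nonreduced", 54.0,
                present=MICROCARPA_4X,
                absent=MICROCARPA_6X,
            ),
        ),
    ),
    absent=_rule(
        "reduced", 12.0,
        present=NEGLECTA,
        absent=_rule(
            "reduced", 33.0,
            present=_rule(
                "reduced", 29.0,
                present=LAXA,
                absent=HISPIDA_GROUP,
            ),
            absent=HISPIDA_GROUP,
        ),
    ),
)

#: Expected leaf label for each generating taxon (subspecies and varieties
#: collapse onto their group leaf).
EXPECTED_LABEL = {
    "C. sativa": SATIVA,
    "C. microcarpa 4X": MICROCARPA_4X,
    "C. microcarpa 6X": MICROCARPA_6X,
    "C. rumelica rumelica": RUMELICA_GROUP,
    "C. rumelica transcapida": RUMELICA_GROUP,
    "C. neglecta": NEGLECTA,
    "C. laxa": LAXA,
    "C. hispida hispida": HISPIDA_GROUP,
    "C. hispida grandiflora": HISPIDA_GROUP,
}


def classify_species(
    reduced: PeakTable,
    nonreduced: PeakTable,
    tree: DecisionRule = SPECIES_TREE,
) -> ClassificationResult:
    """Assign a reduced/non-reduced peak-table pair to a Camelina taxon."""
    if not reduced.peaks and not nonreduced.peaks:
        return ClassificationResult(
            label=None, path=[], unassigned_reason="empty peak tables"
        )
    tables = {"reduced": reduced, "nonreduced": nonreduced}
    node: Union[DecisionRule, str] = tree
    path: list[tuple[str, str]] = []
    while isinstance(node, DecisionRule):
        table = tables[node.condition]
        hit = match_peak(table, node.nominal_kda, node.tol_kda)
        outcome = "present" if hit is not None else "absent"
        path.append((node.describe(), outcome))
        node = node.present if hit is not None else node.absent
    return ClassificationResult(label=node, path=path)


#: "Relatively equal abundance" for the profile-2 doublet: area ratio bounds.
DOUBLET_RATIO_BOUNDS = (0.5, 2.0)
#: "Two large peaks" for profile 3: each at least this percent of total area.
LARGE_PEAK_MIN_PCT = 10.0
#: A profile marker counts as a peak (not trace noise) only above this
#: percent of total area.
MARKER_MIN_PCT = 5.0


def classify_sativa_profile(
    nonreduced: PeakTable,
    trace: Trace,
    tol_kda: float = MATCH_TOL_KDA,
    doublet_ratio_bounds: tuple[float, float] = DOUBLET_RATIO_BOUNDS,
    large_peak_min_pct: float = LARGE_PEAK_MIN_PCT,
    marker_min_pct: float = MARKER_MIN_PCT,
) -> ClassificationResult:
    """Assign a C. sativa sample to non-reducing profile 1, 2 or 3.

    Profile 2 requires the unique ~23 kDa marker plus a ~52/55 kDa doublet
    of comparable abundance; profile 3 two large distinct peaks at ~51 and
    ~54 kDa; profile 1 a single ~51 kDa peak carrying a higher-MW
    shoulder. ``trace`` is the baseline-subtracted non-reducing trace the
    table came from (needed for shoulder geometry). Marker presence
    demands at least ``marker_min_pct`` of total area, so residual noise
    wiggles never count as profile markers.
    """
    path: list[tuple[str, str]] = []
    if not nonreduced.peaks:
        return ClassificationResult(None, [], "empty peak table")

    p23 = match_peak(nonreduced, 23.0, tol_kda)
    if p23 is not None and p23.percent < marker_min_pct:
        p23 = None
    path.append(("23 kDa (nonreduced)", "present" if p23 else "absent"))
    if p23 is not None:
        p52 = match_peak(nonreduced, 52.0, tol_kda)
        p55 = match_peak(nonreduced, 55.0, tol_kda)
        if p52 is not None and p55 is not None and p52 is not p55:
            ratio = p52.area / p55.area
            lo, hi = doublet_ratio_bounds
            ok = lo <= ratio <= hi
            path.append(("52/55 kDa doublet balance", "present" if ok else "absent"))
            if ok:
                return ClassificationResult("Profile 2", path)
        else:
            path.append(("52/55 kDa doublet balance", "absent"))
        return ClassificationResult(
            None, path, "23 kDa marker without a balanced 52/55 doublet"
        )

    p51 = match_peak(nonreduced, 51.0, tol_kda)
    p54 = match_peak(nonreduced, 54.0, tol_kda)
    if p54 is not None and p54 is not p51 and p54.percent < marker_min_pct:
        p54 = None
    two_large = (
        p51 is not None
        and p54 is not None
        and p51 is not p54
        and p51.percent >= large_peak_min_pct
        and p54.percent >= large_peak_min_pct
    )
    path.append(("large 51+54 kDa pair", "present" if two_large else "absent"))
    if two_large:
        return ClassificationResult("Profile 3", path)

    if p51 is not None and (p54 is None or p54 is p51):
        shoulder = detect_shoulder(trace, p51, side="higher")
        path.append(("higher-MW shoulder on 51 kDa", "present" if shoulder else "absent"))
        if shoulder:
            return ClassificationResult("Profile 1", path)
        return ClassificationResult(
            None, path, "single 51 kDa peak without higher-MW shoulder"
        )
    return ClassificationResult(None, path, "no recognised 49-55 kDa pattern")


def batch_classify(
    samples: Sequence[tuple[str, Trace, Trace]],
    tree: DecisionRule = SPECIES_TREE,
) -> tuple[pd.DataFrame, Counter]:
    """Run the full species pipeline over (sample_id, reduced, nonreduced) traces.

    Returns a per-sample result table and counts per label (unassigned
    samples counted under "unassigned").
    """
    rows = []
    counts: Counter = Counter()
    for sample_id, red, nonred in samples:
        t_red = quantify_trace(red, sample_id=sample_id)
        t_non = quantify_trace(nonred, sample_id=sample_id)
        res = classify_species(t_red, t_non, tree)
        label = res.label if res.assigned else "unassigned"
        counts[label] += 1
        rows.append(
            {
                "sample_id": sample_id,
                "label": label,
                "path": "; ".join(f"{r}={o}" for r, o in res.path),
                "unassigned_reason": res.unassigned_reason,
            }
        )
    columns = ["sample_id", "label", "path", "unassigned_reason"]
    return pd.DataFrame(rows, columns=columns), counts


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
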