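"""Meal protein and amino-acid composition statistics.

Reproduces the reporting conventions of seed-meal composition tables:
%w/w amino-acid content (mg of one analyte over total recovered mg),
nitrogen-to-protein conversion (factor 6.25), oven-drying moisture,
coefficient-of-variation QC on technical replicates, one-way ANOVA with
Tukey-Kramer HSD pairwise comparisons, and compact-letter-display
significance categories (groups share a letter iff not significantly
different).

Technical replicates are averaged within biological replicate before
ANOVA; the biological replicate is the experimental unit.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
CV_FLAG_THRESHOLD = 10.0
NITROGEN_FACTOR = 6.25

AA_TABLE_COLUMNS = ("sample_id", "group", "bio_rep", "tech_rep", "analyte", "mg")


def read_aa_table(path) -> pd.DataFrame:
    """Read a long-format amino-acid quantification TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(AA_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"aa table missing columns: {sorted(missing)}")
    return df


def percent_ww(table: pd.DataFrame) -> pd.DataFrame:
    """%w/w per analyte per replicate: 100 * mg / total recovered mg.

    The total runs over the analytes present in each (group, bio, tech)
    replicate; each replicate's percentages sum to 100.
    """
    df = table.copy()
    keys = ["group", "bio_rep", "tech_rep"]
    totals = df.groupby(keys)["mg"].transform("sum")
    if (totals <= 0).any():
        bad = df.loc[totals <= 0, keys].drop_duplicates().to_records(index=False)
        raise ValueError(f"zero total recovered mg in replicate(s): {list(bad)}")
    df["pct_ww"] = 100.0 * df["mg"] / totals
    return df


def average_technical(pct: pd.DataFrame) -> pd.DataFrame:
    """Average %w/w over technical replicates within biological replicate."""
    return (
        pct.groupby(["group", "analyte", "bio_rep"], as_index=False)["pct_ww"]
        .mean()
    )


def group_mean(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD; SD is NaN (undefined) for n < 2."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return mean, sd


def protein_content(nitrogen_pct: float, factor: float = NITROGEN_FACTOR) -> float:
    """Protein percent from nitrogen percent via the conversion factor."""
    if nitrogen_pct < 0:
        raise ValueError("nitrogen_pct must be nonnegative")
    return nitrogen_pct * factor


def moisture_pct(mass_wet: float, mass_dry: float) -> float:
    """Moisture as percent weight loss on drying: 100 * (wet - dry) / wet."""
    if mass_dry <= 0 or mass_wet <= 0:
        raise ValueError("masses must be positive")
    if mass_dry > mass_wet:
        raise ValueError("dry mass exceeds wet mass")
    return 100.0 * (mass_wet - mass_dry) / mass_wet


def cv_flag(
    technical_reps: Sequence[float], threshold: float = CV_FLAG_THRESHOLD
) -> tuple[float, bool]:
    """Coefficient of variation (%) and whether it exceeds the QC threshold."""
    arr = np.asarray(list(technical_reps), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two technical replicates")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean of technical replicates must be positive")
    cv = 100.0 * arr.std(ddof=1) / mean
    return float(cv), bool(cv > threshold)


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def _bron_kerbosch(adj: dict, r: set, p: set, x: set, out: list) -> None:
    if not p and not x:
        out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda v: len(adj[v] & p))
    for v in list(p - adj[pivot]):
        _bron_kerbosch(adj, r | {v}, p & adj[v], x & adj[v], out)
        p.remove(v)
        x.add(v)


_LETTER_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
)


def _assign_letters(groups: Sequence[str], cover: Sequence[frozenset]) -> dict[str, str]:
    ordered = sorted(cover, key=lambda c: min(groups.index(g) for g in c))
    letters = {}
    for g in groups:
        letters[g] = "".join(
            _LETTER_ALPHABET[i] for i, c in enumerate(ordered) if g in c
        )
    return letters


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: set[frozenset],
    exact_max_groups: int = 10,
) -> dict[str, str]:
    """Letters per group: two groups share a letter iff not significantly different.

    Each letter is a clique of the non-significant graph; the assignment
    must cover every group and every non-significant pair. For up to
    ``exact_max_groups`` groups the minimum such cover is found exactly
    (maximal cliques by Bron-Kerbosch, then exhaustive cover search);
    beyond that an insert-and-absorb sweep is used, which is valid but not
    guaranteed minimal.
    """
    groups = list(groups)
    if not groups:
        return {}
    for pair in significant_pairs:
        if not pair <= set(groups) or len(pair) != 2:
            raise ValueError(f"bad significant pair: {set(pair)}")
    nonsig_adj = {
        g: {h for h in groups if h != g and frozenset({g, h}) not in significant_pairs}
        for g in groups
    }
    if len(groups) <= exact_max_groups:
        cliques: list[frozenset] = []
        _bron_kerbosch(nonsig_adj, set(), set(groups), set(), cliques)
        required_edges = {
            frozenset({g, h})
            for g in groups
            for h in nonsig_adj[g]
        }
        # a cover may need more letters than groups (e.g. a cycle of
        # non-significant pairs needs one letter per edge)
        for k in range(1, len(cliques) + 1):
            for combo in itertools.combinations(cliques, k):
                covered_v = set().union(*combo)
                if covered_v != set(groups):
                    continue
                covered_e = {
                    frozenset(p)
                    for c in combo
                    for p in itertools.combinations(c, 2)
                }
                if required_edges <= covered_e:
                    return _assign_letters(groups, combo)
        raise RuntimeError("no letter cover found")  # unreachable
    # insert-and-absorb sweep for many groups
    columns: list[set] = [set(groups)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        columns = [
            c for c in columns
            if not any(c < d for d in columns)
        ]
        # dedupe
        seen, uniq = set(), []
        for c in columns:
            f = frozenset(c)
            if f not in seen:
                seen.add(f)
                uniq.append(c)
        columns = uniq
    return _assign_letters(groups, [frozenset(c) for c in columns])


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupStats:
    """One-way ANOVA summary with Tukey-Kramer pairwise comparisons."""

    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    f_stat: float
    p_value: float
    pairwise_p: dict[frozenset, float]
    letters: dict[str, str]
    alpha: float
    degenerate: bool = False


def anova_tukey(
    groups: dict[str, Sequence[float]], alpha: float = ALPHA
) -> GroupStats:
    """One-way ANOVA with Tukey-Kramer HSD and compact letter display.

    ``groups`` maps group label to replicate values (biological
    replicates). Pairwise p-values use the studentized range distribution
    with pooled variance and the Tukey-Kramer unequal-n correction. If all
    groups have zero within-group variance the result is degenerate: F and
    p are undefined and letters reflect exact mean equality.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(list(groups[g]), dtype=float) for g in labels}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than two replicates")
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}

    if all(sd == 0.0 for sd in sds.values()):
        sig = {
            frozenset({a, b})
            for a, b in itertools.combinations(labels, 2)
            if means[a] != means[b]
        }
        return GroupStats(
            groups=labels, means=means, sds=sds, ns=ns,
            f_stat=float("nan"), p_value=float("nan"),
            pairwise_p={
                frozenset({a, b}): (0.0 if frozenset({a, b}) in sig else 1.0)
                for a, b in itertools.combinations(labels, 2)
            },
            letters=compact_letter_display(labels, sig),
            alpha=alpha, degenerate=True,
        )

    f_stat, p_value = stats.f_oneway(*arrays.values())
    res = stats.tukey_hsd(*arrays.values())
    pairwise: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            pairwise[frozenset({a, labels[j]})] = float(res.pvalue[i, j])
    significant = {pair for pair, p in pairwise.items() if p <= alpha}
    letters = compact_letter_display(labels, significant)
    return GroupStats(
        groups=labels, means=means, sds=sds, ns=ns,
        f_stat=float(f_stat), p_value=float(p_value),
        pairwise_p=pairwise, letters=letters, alpha=alpha,
    )


def composition_report(
    table: pd.DataFrame, alpha: float = ALPHA
) -> pd.DataFrame:
    """Per-analyte group means with SD and significance letters.

    Runs the full chain on a long-format quantification table: %w/w,
    technical averaging, per-analyte ANOVA/Tukey across groups. Returns a
    tidy frame (analyte, group, mean, sd, n, letters) in table style.
    """
    pct = percent_ww(table)
    bio = average_technical(pct)
    rows = []
    for analyte, sub in bio.groupby("analyte", sort=True):
        grp = {
            g: s["pct_ww"].to_numpy()
            for g, s in sub.groupby("group", sort=True)
        }
        st = anova_tukey(grp, alpha=alpha)
        for g in st.groups:
            rows.append(
                {
                    "analyte": analyte,
                    "group": g,
                    "mean": round(st.means[g], 2),
                    "sd": round(st.sds[g], 2),
                    "n": st.ns[g],
                    "letters": st.letters[g],
                }
            )
    return pd.DataFrame(rows)


def write_composition_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
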