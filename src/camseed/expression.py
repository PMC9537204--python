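"""Seed-protein gene expression summaries from count matrices.

Computes transcripts per million (TPM) and quantile-normalised expression
and derives the seed-protein summaries: per-sample cruciferin-type
transcript fractions, sub-genome partitioning of homeologous gene
expression in the allohexaploid genome (sub-genomes G1-G3), and temporal
induction windows (onset/offset intervals on the days-after-anthesis
axis).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RISE_FOLD = 5.0
MIN_TPM = 50.0
SUBGENOMES = ("G1", "G2", "G3")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def read_catalog_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "family", "type", "subgenome", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return df


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    zero_cols = counts.columns[(counts.sum(axis=0) == 0)]
    if len(zero_cols):
        raise ValueError(f"all-zero sample column(s): {list(zero_cols)}")
    rates = counts.div(lengths, axis=0)
    return rates.div(rates.sum(axis=0), axis=1) * 1e6


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each sample's order statistics by their across-sample means.

    Within-sample ranks are preserved; tied values receive the mean of
    their tied quantile values. After normalisation all columns share the
    same sorted values, and the operation is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    positions = np.arange(n, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def family_fraction(
    tpm_matrix: pd.DataFrame, catalog: pd.DataFrame, family: str
) -> pd.DataFrame:
    """Per-sample share of a family's TPM carried by each subtype.

    Shares sum to 1 per sample where the family total is nonzero; samples
    with zero family expression get NaN shares (flagged, not silently 0).
    """
    cat = catalog.set_index("gene_id")
    fam_genes = cat.index[cat["family"] == family]
    if len(fam_genes) == 0:
        raise ValueError(f"family {family!r} not in catalog")
    fam_genes = fam_genes.intersection(tpm_matrix.index)
    sub = tpm_matrix.loc[fam_genes]
    types = cat.loc[fam_genes, "type"]
    by_type = sub.groupby(types).sum()
    totals = by_type.sum(axis=0)
    shares = by_type.div(totals.where(totals > 0), axis=1)
    return shares


def type_fractions_summary(shares: pd.DataFrame) -> pd.Series:
    """Across-sample mean share per subtype, skipping undefined samples."""
    return shares.mean(axis=1, skipna=True)


@dataclasses.dataclass
class SubgenomePartition:
    """Per-sample sub-genome shares of one gene type's expression.

    ``shares`` has one row per sub-genome carrying at least one gene of
    the type; sub-genomes with no such gene are structurally absent (the
    homeologue does not exist) and listed separately rather than reported
    as zero expression.
    """

    type: str
    shares: pd.DataFrame
    structurally_absent: tuple[str, ...]


def subgenome_partition(
    tpm_matrix: pd.DataFrame, catalog: pd.DataFrame, type_label: str
) -> SubgenomePartition:
    """Partition a gene type's TPM across the three sub-genomes."""
    cat = catalog.set_index("gene_id")
    genes = cat.index[cat["type"] == type_label].intersection(tpm_matrix.index)
    if len(genes) == 0:
        raise ValueError(f"type {type_label!r} not in catalog")
    subg = cat.loc[genes, "subgenome"]
    present = tuple(g for g in SUBGENOMES if (subg == g).any())
    if len(present) < 2:
        raise ValueError(
            f"type {type_label!r} present on fewer than two sub-genomes"
        )
    absent = tuple(g for g in SUBGENOMES if g not in present)
    by_sub = tpm_matrix.loc[genes].groupby(subg).sum().reindex(list(present))
    totals = by_sub.sum(axis=0)
    shares = by_sub.div(totals.where(totals > 0), axis=1)
    return SubgenomePartition(
        type=type_label, shares=shares, structurally_absent=absent
    )


@dataclasses.dataclass(frozen=True)
class TemporalWindow:
    """Onset/offset intervals (daa) of an induction time course."""

    onset: tuple[float, float]
    offset: Optional[tuple[float, float]]


def temporal_window(
    series: pd.Series,
    rise_fold: float = RISE_FOLD,
    min_tpm: float = MIN_TPM,
) -> Optional[TemporalWindow]:
    """Find the sharp-induction window of a TPM time course.

    The onset is the first interval (t_i, t_{i+1}) over which expression
    rises by at least ``rise_fold`` (a rise from exactly zero counts as
    sharp) to a level above ``min_tpm``; the offset is the first later
    interval over which it falls by at least the same factor from a level
    above ``min_tpm``. Returns None when no onset is found. The index must
    be numeric, strictly increasing daa values; pooled samples carry no
    time axis and are refused.
    """
    t = np.asarray(series.index, dtype=float)
    if np.isnan(t).any():
        raise ValueError("series index must be numeric daa values (not pooled)")
    if t.size < 4:
        raise ValueError("need at least four timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValueError("daa timepoints must be strictly increasing")
    y = series.to_numpy(dtype=float)

    onset = None
    onset_i = None
    for i in range(t.size - 1):
        if y[i + 1] >= min_tpm and (y[i] <= 0 or y[i + 1] / y[i] >= rise_fold):
            onset = (float(t[i]), float(t[i + 1]))
            onset_i = i
            break
    if onset is None:
        return None
    offset = None
    for j in range(onset_i + 1, t.size - 1):
        if y[j] >= min_tpm and (y[j + 1] <= 0 or y[j] / max(y[j + 1], 1e-300) >= rise_fold):
            offset = (float(t[j]), float(t[j + 1]))
            break
    return TemporalWindow(onset=onset, offset=offset)


def family_windows(
    tpm_matrix: pd.DataFrame,
    catalog: pd.DataFrame,
    timepoints: dict[str, float],
    family: str,
    rise_fold: float = RISE_FOLD,
    min_tpm: float = MIN_TPM,
) -> dict[str, Optional[TemporalWindow]]:
    """Per-gene induction windows for one family over a time course.

    ``timepoints`` maps sample column name to its daa value.
    """
    cat = catalog.set_index("gene_id")
    genes = cat.index[cat["family"] == family].intersection(tpm_matrix.index)
    cols = sorted(timepoints, key=timepoints.get)
    out: dict[str, Optional[TemporalWindow]] = {}
    for g in genes:
        series = pd.Series(
            tpm_matrix.loc[g, cols].to_numpy(),
            index=[timepoints[c] for c in cols],
        )
        out[g] = temporal_window(series, rise_fold, min_tpm)
    return out
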