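"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every input the pipeline consumes:

* multi-Gaussian electropherogram traces from species peak templates that
  carry the discriminating peaks of the Camelina species decision scheme;
* non-reducing trace templates for the three C. sativa seed-protein
  profiles (single ~51 kDa peak with higher-MW shoulder; ~23 kDa marker
  plus a broad ~52/55 doublet; two large ~51/54 peaks);
* random protein sequences with a prescribed residue composition;
* replicate amino-acid quantification tables (mg recovered per analyte)
  with multiplicative technical noise around prescribed %w/w group means;
* negative-binomial count matrices over a seed-development time course
  (0-40 days after anthesis, sampled every 4 days) with a sharp logistic
  induction window and configurable cruciferin-type transcript fractions.

Every generator is a pure function of its spec including the seed; random
streams are per-operation and derived from the seed, so adding one
generator call never shifts another's output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .electropherogram import Trace
from .protchem import STANDARD_RESIDUES, ProteinSeq

# per-operation stream ids (mixed into the numpy seed sequence)
_STREAM_TRACE = 101
_STREAM_SEQ = 202
_STREAM_AA = 303
_STREAM_COUNTS = 404
_STREAM_CATALOG = 505

KDA_GRID = np.arange(5.0, 80.0 + 1e-9, 0.05)
SIGMA_KDA = 0.8          # resolvable at the 2-3 kDa spacing the rules need
NOISE_FRAC = 0.01        # default additive noise: 1% of max clean signal
TRACE_SCALE = 1000.0     # total area units per trace

TAXA = (
    "C. sativa",
    "C. microcarpa 4X",
    "C. microcarpa 6X",
    "C. rumelica rumelica",
    "C. rumelica transcapida",
    "C. neglecta",
    "C. laxa",
    "C. hispida hispida",
    "C. hispida grandiflora",
)

# Peaks shared across all species templates. Nominal sizes are kept >2 kDa
# away from every discriminating nominal so matching at the default 1.5 kDa
# tolerance cannot confuse them.
_COMMON_REDUCED = ((10.0, 1.0), (21.0, 1.5), (26.0, 1.2), (39.0, 2.0), (46.0, 1.0))
_COMMON_NONREDUCED = ((20.0, 1.0), (31.0, 1.2), (39.0, 1.8), (48.0, 2.2))

# Discriminating peaks per taxon (relative weights before normalisation),
# encoding the presence/absence scheme: 17 kDa (reduced) splits the
# sativa/microcarpa/rumelica group from neglecta/laxa/hispida; 14 kDa ->
# sativa; 33 kDa -> rumelica; 54 kDa (non-reduced) -> microcarpa 4X;
# 12 kDa -> neglecta; 33 + 29 kDa -> laxa.
_DISCRIMINATING: dict[str, tuple[tuple[tuple[float, float], ...],
                                 tuple[tuple[float, float], ...]]] = {
    "C. sativa": (((17.0, 1.5), (14.0, 1.2)), ()),
    "C. microcarpa 4X": (((17.0, 1.5),), ((54.0, 1.5),)),
    "C. microcarpa 6X": (((17.0, 1.5),), ()),
    "C. rumelica rumelica": (((17.0, 1.5), (33.0, 1.3)), ()),
    "C. rumelica transcapida": (((17.0, 1.5), (33.0, 1.1)), ()),
    "C. neglecta": (((12.0, 1.4),), ()),
    "C. laxa": (((33.0, 1.3), (29.0, 1.1)), ()),
    "C. hispida hispida": ((), ()),
    "C. hispida grandiflora": ((), ()),
}


def _normalise(peaks: Sequence[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    total = sum(w for _, w in peaks)
    return tuple(sorted((k, w / total) for k, w in peaks))


@dataclasses.dataclass(frozen=True)
class SpeciesTemplate:
    """Noiseless peak sets (nominal kDa, relative abundance) for one taxon."""

    taxon: str
    peaks_reduced: tuple[tuple[float, float], ...]
    peaks_nonreduced: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for peaks in (self.peaks_reduced, self.peaks_nonreduced):
            if not peaks:
                raise ValueError("template condition with no peaks")
            weights = [w for _, w in peaks]
            if any(w <= 0 for w in weights):
                raise ValueError("relative abundances must be positive")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("relative abundances must sum to 1")


def species_template(taxon: str) -> SpeciesTemplate:
    """Template for one of the nine recognised Camelina taxa."""
    if taxon not in _DISCRIMINATING:
        raise ValueError(
            f"unknown taxon {taxon!r}; valid taxa: {', '.join(TAXA)}"
        )
    disc_red, disc_nonred = _DISCRIMINATING[taxon]
    return SpeciesTemplate(
        taxon=taxon,
        peaks_reduced=_normalise(tuple(_COMMON_REDUCED) + tuple(disc_red)),
        peaks_nonreduced=_normalise(
            tuple(_COMMON_NONREDUCED) + tuple(disc_nonred)
        ),
    )


# Non-reducing peak sets for the three C. sativa seed-protein profiles.
# Profile 1: single ~51 kDa peak with an unresolved higher-MW shoulder
# (component at 52.5 kDa, half weight). Profile 2: unique ~23 kDa marker,
# ~36 kDa shoulder on the common 39 kDa peak, broad ~52/55 doublet of
# near-equal abundance. Profile 3: two large peaks at ~51 and ~54 kDa.
_PROFILE_NONREDUCED: dict[int, tuple[tuple[float, float], ...]] = {
    1: ((20.0, 1.0), (31.0, 1.2), (39.0, 1.8), (51.0, 3.0), (52.5, 1.5)),
    2: ((20.0, 1.0), (23.0, 1.2), (31.0, 1.2), (36.5, 0.9), (39.0, 1.8),
        (52.0, 1.3), (55.0, 1.2)),
    3: ((20.0, 1.0), (31.0, 1.2), (39.0, 1.8), (51.0, 2.6), (54.0, 2.3)),
}


def sativa_profile_peaks(profile: int) -> tuple[tuple[float, float], ...]:
    """Non-reducing peak set for C. sativa seed-protein profile 1, 2 or 3."""
    if profile not in _PROFILE_NONREDUCED:
        raise ValueError("profile must be 1, 2 or 3")
    return _normalise(_PROFILE_NONREDUCED[profile])


@dataclasses.dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of one simulated trace pair."""

    template: SpeciesTemplate
    sigma_kda: float = SIGMA_KDA
    noise_sd: Optional[float] = None   # None -> NOISE_FRAC * max clean signal
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_kda <= 0:
            raise ValueError("sigma_kda must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _render_trace(
    peaks: Sequence[tuple[float, float]],
    sigma: float,
    noise_sd: Optional[float],
    baseline: float,
    rng: np.random.Generator,
    condition: str,
) -> Trace:
    grid = KDA_GRID
    sig = np.zeros_like(grid)
    for kda, weight in peaks:
        amp = TRACE_SCALE * weight / (sigma * math.sqrt(2.0 * math.pi))
        sig = sig + amp * np.exp(-0.5 * ((grid - kda) / sigma) ** 2)
    if noise_sd is None:
        noise_sd = NOISE_FRAC * float(sig.max())
    if baseline:
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        sig = sig + baseline * (0.5 + 0.5 * t)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=grid.size)
    return Trace(grid, sig, condition)


def gen_trace(spec: TraceSimSpec) -> tuple[Trace, Trace]:
    """Simulate the (reduced, non-reduced) trace pair for a species template."""
    rng = np.random.default_rng([_STREAM_TRACE, spec.seed])
    reduced = _render_trace(
        spec.template.peaks_reduced, spec.sigma_kda, spec.noise_sd,
        spec.baseline, rng, "reduced",
    )
    nonreduced = _render_trace(
        spec.template.peaks_nonreduced, spec.sigma_kda, spec.noise_sd,
        spec.baseline, rng, "nonreduced",
    )
    return reduced, nonreduced


def gen_profile_trace(
    profile: int,
    sigma_kda: float = SIGMA_KDA,
    noise_sd: Optional[float] = None,
    baseline: float = 0.0,
    seed: int = 0,
) -> Trace:
    """Simulate a non-reducing C. sativa trace for one seed-protein profile."""
    rng = np.random.default_rng([_STREAM_TRACE, profile, seed])
    return _render_trace(
        sativa_profile_peaks(profile), sigma_kda, noise_sd, baseline, rng,
        "nonreduced",
    )


def gen_sequence(length: int, composition: dict[str, float], seed: int = 0) -> ProteinSeq:
    """Random protein sequence drawn from a residue-frequency composition."""
    if length <= 0:
        raise ValueError("length must be positive")
    bad = set(composition) - set(STANDARD_RESIDUES)
    if bad:
        raise ValueError(f"nonstandard residues in composition: {sorted(bad)}")
    residues = sorted(composition)
    freqs = np.array([composition[r] for r in residues], dtype=float)
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("composition frequencies must be >=0 and sum to 1")
    rng = np.random.default_rng([_STREAM_SEQ, seed])
    draw = rng.choice(len(residues), size=length, p=freqs)
    return ProteinSeq(
        id=f"synthetic_{seed}", residues="".join(residues[i] for i in draw)
    )


# ---------------------------------------------------------------------------
# Amino-acid quantification tables
# ---------------------------------------------------------------------------

#: Printed per-accession %w/w means for the C. sativa profile panel
#: (18 recovered analytes; Asx/Glx are combined hydrolysis analytes, Cys as
#: cysteic acid, Met as methionine sulfone). These are the default
#: generating means of `gen_aa_table`.
CAMELINA_AA_MEANS: dict[str, dict[str, float]] = {
    "CN113733": {"Alanine": 4.74, "Arginine": 9.82, "Asx": 9.45,
                 "Cysteic acid": 3.46, "Glx": 17.68, "Glycine": 5.17,
                 "Histidine": 2.73, "Isoleucine": 3.77, "Leucine": 6.93,
                 "Lysine": 5.81, "Methionine": 1.84, "Phenylalanine": 4.36,
                 "Proline": 5.53, "Serine": 4.57, "Threonine": 3.89,
                 "Tryptophan": 1.38, "Tyrosine": 3.20, "Valine": 5.67},
    "CN30476": {"Alanine": 4.89, "Arginine": 9.46, "Asx": 9.40,
                "Cysteic acid": 3.38, "Glx": 17.93, "Glycine": 5.41,
                "Histidine": 2.69, "Isoleucine": 3.71, "Leucine": 6.83,
                "Lysine": 5.86, "Methionine": 1.77, "Phenylalanine": 4.37,
                "Proline": 5.39, "Serine": 4.78, "Threonine": 3.98,
                "Tryptophan": 1.23, "Tyrosine": 3.28, "Valine": 5.64},
    "CN30477": {"Alanine": 4.72, "Arginine": 9.59, "Asx": 9.59,
                "Cysteic acid": 3.13, "Glx": 17.89, "Glycine": 5.50,
                "Histidine": 2.61, "Isoleucine": 4.05, "Leucine": 7.04,
                "Lysine": 5.42, "Methionine": 1.86, "Phenylalanine": 4.42,
                "Proline": 5.26, "Serine": 4.59, "Threonine": 3.94,
                "Tryptophan": 1.32, "Tyrosine": 3.35, "Valine": 5.74},
    "CN45816": {"Alanine": 4.61, "Arginine": 9.98, "Asx": 9.26,
                "Cysteic acid": 3.37, "Glx": 18.63, "Glycine": 5.49,
                "Histidine": 2.67, "Isoleucine": 3.81, "Leucine": 6.85,
                "Lysine": 5.55, "Methionine": 1.75, "Phenylalanine": 4.26,
                "Proline": 5.46, "Serine": 4.52, "Threonine": 3.81,
                "Tryptophan": 1.25, "Tyrosine": 3.18, "Valine": 5.55},
    "CN111331": {"Alanine": 5.01, "Arginine": 9.56, "Asx": 9.49,
                 "Cysteic acid": 3.27, "Glx": 17.45, "Glycine": 5.64,
                 "Histidine": 2.55, "Isoleucine": 3.77, "Leucine": 6.85,
                 "Lysine": 5.80, "Methionine": 1.85, "Phenylalanine": 4.36,
                 "Proline": 5.55, "Serine": 4.71, "Threonine": 3.95,
                 "Tryptophan": 1.25, "Tyrosine": 3.23, "Valine": 5.69},
    "CN114265": {"Alanine": 4.63, "Arginine": 9.78, "Asx": 9.09,
                 "Cysteic acid": 3.95, "Glx": 17.98, "Glycine": 5.53,
                 "Histidine": 2.66, "Isoleucine": 3.72, "Leucine": 6.85,
                 "Lysine": 5.52, "Methionine": 2.02, "Phenylalanine": 4.33,
                 "Proline": 5.49, "Serine": 4.54, "Threonine": 3.81,
                 "Tryptophan": 1.31, "Tyrosine": 3.21, "Valine": 5.55},
}


def gen_aa_table(
    group_means: Optional[dict[str, dict[str, float]]] = None,
    cv_tech: float = 5.0,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    total_mg: float = 100.0,
) -> pd.DataFrame:
    """Per-replicate recovered-mg table with prescribed %w/w group means.

    Technical noise is multiplicative lognormal with the stated coefficient
    of variation and unit mean, so the expected %w/w of each analyte in
    each group equals the generating mean. ``cv_tech`` is in percent.
    Returns a long DataFrame (sample_id, group, bio_rep, tech_rep,
    analyte, mg).
    """
    if group_means is None:
        group_means = CAMELINA_AA_MEANS
    if cv_tech < 0:
        raise ValueError("cv_tech must be nonnegative")
    for g, means in group_means.items():
        if any(m <= 0 for m in means.values()):
            raise ValueError(f"group {g!r} has a nonpositive mean")
    rng = np.random.default_rng([_STREAM_AA, seed])
    cv = cv_tech / 100.0
    s2 = math.log1p(cv * cv)
    rows = []
    for group in sorted(group_means):
        means = group_means[group]
        analytes = sorted(means)
        base = np.array([means[a] for a in analytes]) / 100.0 * total_mg
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                if cv > 0:
                    factors = rng.lognormal(
                        mean=-0.5 * s2, sigma=math.sqrt(s2), size=base.size
                    )
                else:
                    factors = np.ones(base.size)
                mg = base * factors
                for a, m in zip(analytes, mg):
                    rows.append(
                        {
                            "sample_id": f"{group}_b{b}_t{t}",
                            "group": group,
                            "bio_rep": b,
                            "tech_rep": t,
                            "analyte": a,
                            "mg": float(m),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene catalogue and count matrices
# ---------------------------------------------------------------------------

def build_catalog(n_other: int = 300, seed: int = 0) -> pd.DataFrame:
    """Seed-protein gene catalogue for the allohexaploid C. sativa genome.

    Encodes the family structure of the reference annotation: 12 cruciferin
    genes (CruA: two tandem copies on G1 plus one on G2, no G3 homeologue;
    CruB, CruC, CruD: one per sub-genome), 8 napins (clusters of four on G1
    and G3, none on G2), 8 vicilins (Vic1A on all three sub-genomes, Vic1B
    on G2 and G3 only, Vic2 on all three) and 12 oleosins (Ole-1..4 on each
    sub-genome), plus ``n_other`` background genes. Transcript lengths are
    drawn once per catalogue seed.
    """
    entries: list[tuple[str, str, str, str]] = []
    entries += [
        ("CsCruA-1-G1", "cruciferin", "CruA", "G1"),
        ("CsCruA-2-G1", "cruciferin", "CruA", "G1"),
        ("CsCruA-1-G2", "cruciferin", "CruA", "G2"),
    ]
    for t in ("CruB", "CruC", "CruD"):
        for g in ("G1", "G2", "G3"):
            entries.append((f"Cs{t}-1-{g}", "cruciferin", t, g))
    for g in ("G1", "G3"):
        for i in range(1, 5):
            entries.append((f"CsNap-{i}-{g}", "napin", f"Nap-{i}", g))
    for g in ("G1", "G2", "G3"):
        entries.append((f"CsVic1A-1-{g}", "vicilin", "Vic1A", g))
    for g in ("G2", "G3"):
        entries.append((f"CsVic1B-1-{g}", "vicilin", "Vic1B", g))
    for g in ("G1", "G2", "G3"):
        entries.append((f"CsVic2-1-{g}", "vicilin", "Vic2", g))
    for i in range(1, 5):
        for g in ("G1", "G2", "G3"):
            entries.append((f"CsOle-{i}-{g}", "oleosin", f"Ole-{i}", g))
    for j in range(1, n_other + 1):
        entries.append((f"gene{j:04d}", "other", "other", "unassigned"))

    rng = np.random.default_rng([_STREAM_CATALOG, seed])
    lengths = rng.integers(900, 2500, size=len(entries))
    return pd.DataFrame(
        {
            "gene_id": [e[0] for e in entries],
            "family": [e[1] for e in entries],
            "type": [e[2] for e in entries],
            "subgenome": [e[3] for e in entries],
            "length_bp": lengths,
        }
    )


#: Plateau-phase share of the transcript pool per seed-protein family.
FAMILY_BUDGET = {"cruciferin": 0.30, "napin": 0.15, "vicilin": 0.05,
                 "oleosin": 0.05}

#: Steepness (daa) of the logistic induction edges; small enough that
#: expression at the onset-interval start stays a few-1e-5 of plateau even
#: after per-sample TPM renormalisation ("near zero" before onset).
INDUCTION_SCALE = 0.2


@dataclasses.dataclass(frozen=True)
class CountSimSpec:
    """Parameters of one simulated expression time course."""

    catalog: pd.DataFrame
    timepoints: tuple[int, ...] = tuple(range(0, 41, 4))
    type_fractions: tuple[float, float, float, float] = (0.55, 0.42, 0.02, 0.01)
    onset_daa: int = 8
    offset_daa: int = 28
    libsize: float = 1e6
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        tf = self.type_fractions
        if len(tf) != 4 or any(f < 0 for f in tf) or abs(sum(tf) - 1.0) > 1e-9:
            raise ValueError("type_fractions must be 4 nonnegative values summing to 1")
        if not self.onset_daa < self.offset_daa:
            raise ValueError("onset_daa must precede offset_daa")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def induction_shape(t: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """Logistic rise centred at onset+2 and fall centred at offset+2."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(t - (onset + 2.0)) / INDUCTION_SCALE))
    fall = 1.0 / (1.0 + np.exp((t - (offset + 2.0)) / INDUCTION_SCALE))
    return rise * fall


def expected_tpm(spec: CountSimSpec) -> pd.DataFrame:
    """Noise-free expected TPM profile (genes x timepoints)."""
    cat = spec.catalog
    t = np.array(spec.timepoints, dtype=float)
    shape = induction_shape(t, spec.onset_daa, spec.offset_daa)
    total = 1e6
    cru_types = ("CruA", "CruB", "CruC", "CruD")
    plateau = np.zeros(len(cat))
    other_mask = (cat["family"] == "other").to_numpy()
    # seed-protein families: fixed plateau budget, split within family
    for fam, budget in FAMILY_BUDGET.items():
        fam_mask = (cat["family"] == fam).to_numpy()
        if fam == "cruciferin":
            for frac, ctype in zip(spec.type_fractions, cru_types):
                m = fam_mask & (cat["type"] == ctype).to_numpy()
                if m.sum():
                    plateau[m] = total * budget * frac / m.sum()
        else:
            plateau[fam_mask] = total * budget / fam_mask.sum()
    # background genes: flat in time, filling the remaining budget with a
    # deterministic spread of levels
    n_other = int(other_mask.sum())
    other_budget = total * (1.0 - sum(FAMILY_BUDGET.values()))
    levels = np.linspace(0.2, 1.8, n_other)
    plateau[other_mask] = other_budget * levels / levels.sum()

    profile = np.outer(plateau, shape)
    profile[other_mask, :] = plateau[other_mask, None]
    cols = [f"d{int(x):02d}" for x in spec.timepoints]
    return pd.DataFrame(profile, index=cat["gene_id"].to_numpy(), columns=cols)


def gen_counts(
    spec: CountSimSpec, pooled: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts and gene lengths for a simulated time course.

    Expected counts per sample are proportional to expected TPM times
    transcript length, scaled to the library size. ``dispersion`` is the
    negative-binomial dispersion (variance mu + dispersion * mu^2);
    dispersion 0 gives deterministic rounded expectations. With
    ``pooled=True`` a single sample is generated whose expectation is the
    equal-weight average of the per-timepoint expectations (the pooled
    boll design; no temporal information survives pooling).
    """
    tpm_exp = expected_tpm(spec)
    lengths = pd.Series(
        spec.catalog["length_bp"].to_numpy(),
        index=spec.catalog["gene_id"].to_numpy(),
        name="length_bp",
    )
    if pooled:
        tpm_exp = tpm_exp.mean(axis=1).to_frame("pooled")
    weights = tpm_exp.mul(lengths, axis=0)
    mu = weights.div(weights.sum(axis=0), axis=1) * spec.libsize
    rng = np.random.default_rng([_STREAM_COUNTS, spec.seed])
    if spec.dispersion == 0:
        counts = np.round(mu.to_numpy()).astype(int)
    else:
        n = 1.0 / spec.dispersion
        m = mu.to_numpy()
        p = np.where(m > 0, n / (n + m), 1.0)
        counts = rng.negative_binomial(n, p)
        counts[m == 0] = 0
    out = pd.DataFrame(counts, index=tpm_exp.index, columns=tpm_exp.columns)
    return out, lengths


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_catalog_tsv(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def write_aa_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Sequence[ProteinSeq], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i: i + 60] + "\n")
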