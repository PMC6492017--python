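"""Synthetic cohort generator with the statistical structure the analysis assumes.

Produces matched segmented copy-number profiles, a clinical table, an
RNA-seq count matrix, and (separately) an array-intensity matrix, together
with the latent truth (true LoY state, true arm events, true purity) so
every downstream stage can be tested against known ground truth.

Generative model, per male sample: the tumor carries Y copy number 0 in a
``subclonal_loy_fraction`` of cells when the sample is LoY and 1 otherwise;
the observed segment value is the purity mixture
``purity * CN_tumor + (1 - purity) * CN_normal`` plus Gaussian noise.
Female samples carry no Y segments. Autosomal arm gains/losses are drawn at
a Poisson rate that differs between LoY and non-LoY samples; survival times
are exponential with a multiplicative LoY hazard; Y-gene counts are
negative-binomial with means proportional to the purity-mixed Y copy
number. All randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .cn_index import AUTOSOMES, GenomeArms, SegmentRecord, VALUE_SCALES

_LOG2_FLOOR = 1e-6  # linear CN floor before log2 emission

_SUBSTREAMS = ("clinical", "segments", "counts", "array")

SMOKING_CATEGORIES = (
    "never_smoked",
    "stopped_gt15y",
    "stopped_lt15y",
    "current_smoker",
)

SITES = ("oral_cavity", "larynx", "oropharynx", "hypopharynx")


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic cohort."""

    n_samples: int = 400
    female_fraction: float = 0.27
    loy_prevalence: float = 0.25
    subclonal_loy_fraction: float = 0.5
    purity_alpha: float = 8.0
    purity_beta: float = 2.0
    fixed_purity: float | None = None  # overrides the Beta purity law when set
    arm_event_rate_loy: float = 8.0
    arm_event_rate_nonloy: float = 3.0
    segment_noise_sd: float = 0.05
    hpv_positive_fraction: float = 0.23
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    loy_hazard_ratio: float = 2.0
    censoring_rate: float = 1.0 / 2500.0
    n_genes: int = 2000
    n_y_genes: int = 12
    n_immune_genes: int = 100
    n_redox_genes: int = 50
    nb_dispersion: float = 0.1
    redox_log2fc: float = 1.0
    immune_log2fc: float = 1.0
    smoking_loy_association: float = 0.5
    value_scale: str = "log2ratio"
    # microarray branch
    array_normal_fraction: float = 0.20
    array_dysplasia_fraction: float = 0.05
    array_background: float = 50.0
    array_signal: float = 500.0
    array_noise_sd: float = 25.0
    array_n_probes: int = 7
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first invalid field."""
        proportions = (
            "female_fraction", "loy_prevalence", "subclonal_loy_fraction",
            "hpv_positive_fraction", "array_normal_fraction",
            "array_dysplasia_fraction",
        )
        for name in proportions:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        positive = (
            "purity_alpha", "purity_beta", "arm_event_rate_loy",
            "arm_event_rate_nonloy", "baseline_hazard", "loy_hazard_ratio",
            "nb_dispersion", "array_signal",
        )
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("segment_noise_sd", "censoring_rate", "array_noise_sd",
                     "array_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_samples", "n_genes", "n_y_genes", "n_immune_genes",
                     "n_redox_genes", "array_n_probes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_y_genes + self.n_immune_genes + self.n_redox_genes > self.n_genes:
            raise ValueError(
                "n_y_genes + n_immune_genes + n_redox_genes must be <= n_genes"
            )
        if self.fixed_purity is not None and not 0 < self.fixed_purity <= 1:
            raise ValueError(f"fixed_purity must be in (0, 1], got {self.fixed_purity}")
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(
                f"value_scale must be one of {VALUE_SCALES}, got {self.value_scale!r}"
            )

    def rng(self, substream: str) -> np.random.Generator:
        """Named child generator; modules can be regenerated independently."""
        key = _SUBSTREAMS.index(substream)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass
class CohortBundle:
    """Matched synthetic datasets plus per-sample latent truth."""

    segments: list[SegmentRecord]
    clinical: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _gene_names(config: SimulationConfig) -> list[str]:
    names = [f"YG{i:04d}" for i in range(config.n_y_genes)]
    names += [f"IMM{i:04d}" for i in range(config.n_immune_genes)]
    names += [f"REDOX{i:04d}" for i in range(config.n_redox_genes)]
    n_rest = config.n_genes - len(names)
    names += [f"G{i:05d}" for i in range(n_rest)]
    return names


def simulate_cohort(config: SimulationConfig, genome: GenomeArms | None = None) -> CohortBundle:
    """Generate a full synthetic cohort (segments, clinical, counts, truth)."""
    config.validate()
    genome = genome or GenomeArms.grch37()

    # --- clinical substream: sex, HPV, purity, LoY, covariates, survival
    rng = config.rng("clinical")
    n = config.n_samples
    sample_ids = [f"SYN{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    hpv = np.where(rng.random(n) < config.hpv_positive_fraction, "positive", "negative")
    if config.fixed_purity is not None:
        purity = np.full(n, config.fixed_purity)
    else:
        purity = np.clip(rng.beta(config.purity_alpha, config.purity_beta, size=n),
                         0.05, 1.0)
    true_loy = (sex == "male") & (rng.random(n) < config.loy_prevalence)

    smoking = np.empty(n, dtype=object)
    base_p = np.array([0.25, 0.15, 0.25, 0.35])
    tilt = base_p * np.exp(config.smoking_loy_association * np.arange(4) / 3.0)
    tilt = tilt / tilt.sum()
    for i in range(n):
        p = tilt if true_loy[i] else base_p
        smoking[i] = SMOKING_CATEGORIES[rng.choice(4, p=p)]

    tp53 = np.where(
        hpv == "negative", rng.random(n) < 0.85, rng.random(n) < 0.25
    ).astype(int)
    age = np.round(rng.normal(61, 11, size=n)).clip(25, 90).astype(int)
    site = np.array(SITES, dtype=object)[rng.choice(4, size=n, p=[0.55, 0.25, 0.18, 0.02])]
    path_t = np.array(["T1", "T2", "T3", "T4"], dtype=object)[
        rng.choice(4, size=n, p=[0.15, 0.3, 0.25, 0.3])
    ]
    path_n = np.array(["N0", "N1", "N2", "N3"], dtype=object)[
        rng.choice(4, size=n, p=[0.4, 0.2, 0.35, 0.05])
    ]

    hazard = config.baseline_hazard * np.where(true_loy, config.loy_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "hpv_status": hpv,
            "tumor_nuclei_percent": np.round(purity * 100.0, 2),
            "smoking_history": smoking,
            "age": age,
            "tp53_mutated": tp53,
            "anatomic_site": site,
            "pathologic_t": path_t,
            "pathologic_n": path_n,
            "survival_days": np.round(time, 1),
            "death_observed": event,
        }
    ).set_index("sample_id")

    # --- segments substream: autosomal arm events, X, Y
    rng = config.rng("segments")
    included_arms = genome.autosomal_arms()
    segments: list[SegmentRecord] = []
    n_events = np.zeros(n, dtype=int)
    event_strings = []
    noise_sd = config.segment_noise_sd

    def observed(tumor_cn: float, normal_cn: float, p: float) -> float:
        value = p * tumor_cn + (1.0 - p) * normal_cn
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        return max(value, 0.0)

    def emit(sample: str, chrom: str, start: int, end: int, linear_cn: float) -> None:
        if config.value_scale == "log2ratio":
            value = math.log2(max(linear_cn, _LOG2_FLOOR) / 2.0)
        else:
            value = linear_cn
        segments.append(SegmentRecord(sample, chrom, start, end, None, value))

    for i, sample in enumerate(sample_ids):
        p = purity[i]
        rate = config.arm_event_rate_loy if true_loy[i] else config.arm_event_rate_nonloy
        k = min(rng.poisson(rate), len(included_arms))
        n_events[i] = k
        hit = rng.choice(len(included_arms), size=k, replace=False)
        deltas = rng.choice([-1, 1], size=k)
        delta_by_arm = {included_arms[j].name: int(d) for j, d in zip(hit, deltas)}
        event_strings.append(
            ";".join(f"{a}{'+' if d > 0 else '-'}" for a, d in sorted(delta_by_arm.items()))
        )
        for arm in included_arms:
            tumor_cn = 2 + delta_by_arm.get(arm.name, 0)
            emit(sample, arm.chromosome, arm.start, arm.end, observed(tumor_cn, 2.0, p))
        # X: one copy in males (normal and tumor), two in females
        x_cn = 1.0 if sex[i] == "male" else 2.0
        for arm in genome.arms_of("X"):
            emit(sample, "X", arm.start, arm.end, observed(x_cn, x_cn, p))
        # Y: males only; females emit no Y rows (matches real SEG output)
        if sex[i] == "male":
            tumor_y = 1.0 - config.subclonal_loy_fraction if true_loy[i] else 1.0
            for arm in genome.arms_of("Y"):
                emit(sample, "Y", arm.start, arm.end, observed(tumor_y, 1.0, p))

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "true_loy": true_loy.astype(int),
            "true_purity": purity,
            "n_arm_events": n_events,
            "arm_events": event_strings,
            "subclonal_loy_fraction": np.where(
                true_loy, config.subclonal_loy_fraction, 0.0
            ),
        }
    ).set_index("sample_id")

    # --- counts substream: NB counts with dosage / immune / redox structure
    rng = config.rng("counts")
    genes = _gene_names(config)
    base_mean = np.exp(rng.normal(math.log(100.0), 1.0, size=config.n_genes))
    mixed_y = np.where(
        sex == "male",
        purity * np.where(true_loy, 1.0 - config.subclonal_loy_fraction, 1.0)
        + (1.0 - purity) * 1.0,
        0.0,
    )
    aneu_norm = n_events / max(1, n_events.max())
    mu = np.tile(base_mean[:, None], (1, n))
    ny, ni, nr = config.n_y_genes, config.n_immune_genes, config.n_redox_genes
    if ny:
        mu[:ny, :] = base_mean[:ny, None] * np.maximum(mixed_y[None, :], 0.01)
    if ni:
        mu[ny:ny + ni, :] *= 2.0 ** (-config.immune_log2fc * aneu_norm[None, :])
    if nr:
        mu[ny + ni:ny + ni + nr, :] *= np.where(true_loy[None, :],
                                                2.0 ** config.redox_log2fc, 1.0)
    size = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    return CohortBundle(segments=segments, clinical=clinical, counts=counts_df,
                        truth=truth, config=config)


def simulate_microarray(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probe x sample intensity matrix plus a sample table.

    Discriminating-probe intensities are ``background + noise`` for females
    and ``background + signal * dosage + noise`` for males, where the dosage
    is 1 except for LoY tumors, which are scaled by
    ``1 - subclonal_loy_fraction * purity``.
    """
    config.validate()
    rng = config.rng("array")
    n = config.n_samples
    sample_ids = [f"ARR{i:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    u = rng.random(n)
    group = np.where(
        u < config.array_normal_fraction,
        "normal",
        np.where(u < config.array_normal_fraction + config.array_dysplasia_fraction,
                 "dysplasia", "tumor"),
    )
    if (sex == "female").sum() < 2:
        raise ValueError("simulate_microarray requires >= 2 female samples")
    if ((sex == "male") & (group == "normal")).sum() < 2:
        raise ValueError("simulate_microarray requires >= 2 male normal samples")

    if config.fixed_purity is not None:
        purity = np.full(n, config.fixed_purity)
    else:
        purity = np.clip(rng.beta(config.purity_alpha, config.purity_beta, size=n),
                         0.05, 1.0)
    purity = np.where(group == "tumor", purity, 1.0)
    true_loy = (sex == "male") & (group == "tumor") & (rng.random(n) < config.loy_prevalence)
    dosage = np.where(
        sex == "male",
        np.where(true_loy, 1.0 - config.subclonal_loy_fraction * purity, 1.0),
        0.0,
    )
    probes = [f"yprobe_{i + 1}" for i in range(config.array_n_probes)]
    signal = np.tile(config.array_background + config.array_signal * dosage,
                     (config.array_n_probes, 1))
    if config.array_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.array_noise_sd,
                                     size=(config.array_n_probes, n))
    intensities = pd.DataFrame(signal, index=probes, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "group": group,
            "true_loy": true_loy.astype(int),
            "purity": purity,
        }
    ).set_index("sample_id")
    return intensities, samples


# ---------------------------------------------------------------------------
# Writers (all plain tab-separated text)


def write_seg(segments: list[SegmentRecord], path: str | Path) -> None:
    """Write segments as SEG (1-based inclusive coordinates)."""
    rows = [
        {
            "Sample": s.sample_id,
            "Chromosome": s.chromosome,
            "Start": s.start + 1,
            "End": s.end,
            "Num_Probes": s.n_markers if s.n_markers is not None else "",
            "Segment_Mean": f"{s.value:.6f}",
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as SEG + TSV files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.seg",
        "clinical": out / "clinical.tsv",
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
    }
    write_seg(bundle.segments, paths["segments"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t")
    bundle.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    bundle.truth.to_csv(paths["truth"], sep="\t")
    return paths
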