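"""End-to-end orchestration: indices -> LoY calls -> associations -> DE.

Runs per HPV stratum: compute purity-adjusted indices from segmented data,
fit the bimodal Y-index density and classify males as LOY / RETAINED /
UNCERTAIN, then (where the clinical table allows) run the stratified
association battery, LoY-vs-retained survival, differential expression, and
gene-set enrichment. Emits a :class:`ReportBundle` of plain TSV-able tables
plus run metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
import tempfile
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc_stats, expression
from .cn_index import GenomeArms, linearize, read_seg, sample_indices, segments_by_sample
from .loy_call import LOY, RETAINED, UnimodalityError, classify_loy, fit_bimodal

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds, and knobs for a full analysis run."""

    seg: str
    clinical: str
    counts: str | None = None
    gmt: str | None = None
    value_scale: str = "log2ratio"
    bandwidth: float | None = None
    min_separation: float = 0.2
    de_p_hpv_negative: float = 0.01
    de_p_hpv_positive: float = 0.05
    fc_threshold: float = 1.5
    cpm_floor: float = 1.0
    exclude_21p: bool = False
    out_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("de_p_hpv_negative", "de_p_hpv_positive"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("seg", "clinical"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        for name in ("counts", "gmt"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")


@dataclass
class ReportBundle:
    """All tables produced by one run, keyed for serialization."""

    indices: pd.DataFrame
    calls: dict[str, pd.DataFrame] = field(default_factory=dict)
    density: dict[str, pd.DataFrame] = field(default_factory=dict)
    tests: pd.DataFrame | None = None
    de: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """Deterministic digest of every table, for reproducibility checks."""
        digest = hashlib.sha256()
        for name, frame in sorted(self._tables().items()):
            digest.update(name.encode())
            digest.update(frame.to_csv(float_format="%.10g").encode())
        return digest.hexdigest()

    def _tables(self) -> dict[str, pd.DataFrame]:
        tables: dict[str, pd.DataFrame] = {"indices": self.indices}
        for stratum, frame in self.calls.items():
            tables[f"{stratum}/loy_calls"] = frame
        for stratum, frame in self.density.items():
            tables[f"{stratum}/density"] = frame
        if self.tests is not None:
            tables["tests"] = self.tests
        for name, frame in self.de.items():
            tables[f"de/{name}"] = frame
        for name, frame in self.enrichment.items():
            tables[f"enrichment/{name}"] = frame
        return tables


def _required(clinical: pd.DataFrame, columns: list[str]) -> bool:
    return all(c in clinical.columns for c in columns)


def run_analysis(config: PipelineConfig, genome: GenomeArms | None = None) -> ReportBundle:
    """Execute the full stratified analysis described by ``config``."""
    config.validate()
    np.random.seed(config.seed)  # nothing below should draw, but pin anyway
    genome = genome or GenomeArms.grch37(exclude_21p=config.exclude_21p)

    clinical = pd.read_csv(config.clinical, sep="\t", index_col="sample_id")
    if "sex" not in clinical.columns:
        raise ValueError("clinical table must contain a 'sex' column")
    records = read_seg(config.seg, value_scale=config.value_scale)
    per_sample = segments_by_sample(linearize(records, config.value_scale))

    purity = {}
    if "tumor_nuclei_percent" in clinical.columns:
        purity = {
            s: v / 100.0
            for s, v in clinical["tumor_nuclei_percent"].items()
            if np.isfinite(v) and v > 0
        }
    sex_map = clinical["sex"].to_dict()
    indices = sample_indices(per_sample, genome, purity=purity, sex=sex_map)

    counts = None
    cpm = None
    if config.counts:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        cpm = expression.cpm_normalize(counts)
    gene_sets = expression.read_gmt(config.gmt) if config.gmt else None

    if "hpv_status" in clinical.columns:
        strata = {
            f"hpv_{value}": clinical.index[clinical["hpv_status"] == value]
            for value in sorted(clinical["hpv_status"].dropna().unique())
        }
    else:
        logger.warning("no hpv_status column; analyzing a single stratum")
        strata = {"all": clinical.index}

    bundle = ReportBundle(indices=indices)
    test_rows: list[dict] = []
    annotations: list[str] = []

    for stratum, members in strata.items():
        males = [
            s for s in members
            if sex_map.get(s) == "male" and s in indices.index
        ]
        y = indices.loc[males, "y_index"].dropna()
        if len(y) < 20:
            annotations.append(f"{stratum}: skipped ({len(y)} male Y indices < 20)")
            continue
        try:
            fit = fit_bimodal(y.values, bandwidth=config.bandwidth,
                              min_separation=config.min_separation)
        except UnimodalityError as exc:
            annotations.append(f"{stratum}: unimodal Y-index distribution ({exc})")
            continue
        calls = classify_loy(y, fit)
        bundle.calls[stratum] = calls
        bundle.density[stratum] = pd.DataFrame(
            {"y_index": fit.grid, "density": fit.density}
        )

        sub = clinical.loc[[s for s in members if s in clinical.index]]
        stratum_calls = calls.join(indices[["aneuploidy_index"]])
        confident = stratum_calls[stratum_calls["label"].isin([LOY, RETAINED])]
        test_rows += _stratum_tests(stratum, sub, stratum_calls, confident, annotations)

        if cpm is not None:
            p_thr = (config.de_p_hpv_negative if "negative" in stratum
                     else config.de_p_hpv_positive)
            test_rows_de = _stratum_de(
                stratum, confident, indices, males, cpm, gene_sets, p_thr,
                config, bundle, annotations,
            )
            test_rows += test_rows_de

    bundle.tests = pd.DataFrame(
        test_rows, columns=["stratum", "test", "statistic", "p_value", "n", "note"]
    ).set_index(["stratum", "test"]) if test_rows else pd.DataFrame(
        columns=["stratum", "test", "statistic", "p_value", "n", "note"]
    ).set_index(["stratum", "test"])

    bundle.metadata = {
        "tool": "loyscan",
        "version": __version__,
        "seed": config.seed,
        "python": platform.python_version(),
        "config": {f.name: getattr(config, f.name) for f in dataclass_fields(config)},
        "n_samples_clinical": int(len(clinical)),
        "n_samples_segmented": int(len(per_sample)),
        "strata": {name: int(len(v)) for name, v in strata.items()},
        "annotations": annotations,
    }
    return bundle


def _stratum_tests(stratum, clinical, calls, confident, annotations) -> list[dict]:
    """LoY association battery for one stratum; skips tests gracefully."""
    rows = []

    def add(test, result, note=""):
        rows.append({"stratum": stratum, "test": test, "statistic": result.statistic,
                     "p_value": result.p_value, "n": result.n, "note": note})

    merged = confident.join(clinical, how="inner")
    full = calls.join(clinical, how="inner")

    if _required(clinical, ["survival_days", "death_observed"]):
        loy_labels = merged["label"]
        if loy_labels.nunique() == 2 and merged["death_observed"].sum() > 0:
            try:
                add("logrank_loy_vs_retained", assoc_stats.logrank_test(
                    merged["survival_days"], merged["death_observed"], loy_labels))
            except ValueError as exc:
                annotations.append(f"{stratum}: logrank skipped ({exc})")
        try:
            cox = assoc_stats.cox_fit(
                full[["survival_days", "death_observed", "y_index"]],
                "survival_days", "death_observed", ["y_index"],
            )
            rows.append({
                "stratum": stratum, "test": "cox_univariate_y_index",
                "statistic": float(cox.loc["y_index", "coef"]),
                "p_value": float(cox.loc["y_index", "p_value"]),
                "n": cox.attrs["n"], "note": "statistic = log hazard ratio",
            })
        except (ValueError, assoc_stats.FitError) as exc:
            annotations.append(f"{stratum}: Cox skipped ({exc})")
    else:
        annotations.append(f"{stratum}: survival columns missing; survival section absent")

    if "smoking_history" in full.columns and full["smoking_history"].nunique() > 1:
        add("kruskal_smoking_vs_y_index", assoc_stats.kruskal_wallis(
            full["y_index"], full["smoking_history"]))
    if "age" in full.columns:
        add("spearman_age_vs_y_index", assoc_stats.spearman(full["age"], full["y_index"]))
    if "pathologic_t" in full.columns and full["pathologic_t"].nunique() > 1:
        add("kruskal_pathologic_t_vs_y_index", assoc_stats.kruskal_wallis(
            full["y_index"], full["pathologic_t"]))

    if "aneuploidy_index" in merged.columns and merged["label"].nunique() == 2:
        add("wilcoxon_aneuploidy_loy_vs_retained", assoc_stats.wilcoxon_rank_sum(
            merged.loc[merged["label"] == LOY, "aneuploidy_index"],
            merged.loc[merged["label"] == RETAINED, "aneuploidy_index"]))

    if "tp53_mutated" in merged.columns and merged["label"].nunique() == 2:
        tab = pd.crosstab(merged["label"] == LOY, merged["tp53_mutated"] == 1)
        if tab.shape == (2, 2):
            add("fisher_tp53_vs_loy", assoc_stats.fisher_exact(tab.values),
                note="statistic = odds ratio")
    return rows


def _stratum_de(stratum, confident, indices, males, cpm, gene_sets, p_thr,
                config, bundle, annotations) -> list[dict]:
    """LoY and aneuploidy-tercile DE plus enrichment for one stratum."""
    rows: list[dict] = []
    loy_ids = [s for s in confident.index[confident["label"] == LOY] if s in cpm.columns]
    ret_ids = [s for s in confident.index[confident["label"] == RETAINED] if s in cpm.columns]
    if len(loy_ids) >= 3 and len(ret_ids) >= 3:
        de = expression.de_test(cpm, loy_ids, ret_ids, p_threshold=p_thr,
                                fc_threshold=config.fc_threshold,
                                cpm_floor=config.cpm_floor)
        bundle.de[f"{stratum}_loy_vs_retained"] = de
        if gene_sets:
            hits_up = de.index[de["passes_filters"] & (de["log2_fold_change"] > 0)]
            hits_down = de.index[de["passes_filters"] & (de["log2_fold_change"] < 0)]
            universe = de.index
            for direction, hits in (("up", hits_up), ("down", hits_down)):
                if len(hits):
                    bundle.enrichment[f"{stratum}_loy_{direction}"] = expression.enrich(
                        hits, universe, gene_sets)
    else:
        annotations.append(
            f"{stratum}: LoY DE skipped ({len(loy_ids)} LOY vs {len(ret_ids)} RETAINED)")

    # aneuploidy top vs bottom thirds among males with counts
    aneu = indices.loc[[s for s in males if s in cpm.columns], "aneuploidy_index"].dropna()
    if len(aneu) >= 9:
        order = aneu.sort_values(kind="stable")
        third = len(order) // 3
        bottom = list(order.index[:third])
        top = list(order.index[-third:])
        if third >= 3:
            de = expression.de_test(cpm, top, bottom, p_threshold=p_thr,
                                    fc_threshold=config.fc_threshold,
                                    cpm_floor=config.cpm_floor)
            bundle.de[f"{stratum}_aneuploidy_top_vs_bottom"] = de
            if gene_sets:
                hits_up = de.index[de["passes_filters"] & (de["log2_fold_change"] > 0)]
                hits_down = de.index[de["passes_filters"] & (de["log2_fold_change"] < 0)]
                for direction, hits in (("up", hits_up), ("down", hits_down)):
                    if len(hits):
                        bundle.enrichment[f"{stratum}_aneuploidy_{direction}"] = (
                            expression.enrich(hits, de.index, gene_sets))
    return rows


def _atomic_write(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as handle:
        handle.write(text)
    os.replace(tmp, path)


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write all bundle tables as TSV plus metadata JSON and a text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in bundle._tables().items():
        path = out / (name.replace("/", "__") + ".tsv")
        _atomic_write(frame.to_csv(sep="\t", float_format="%.10g"), path)
        written.append(path)
    meta_path = out / "run_metadata.json"
    _atomic_write(json.dumps(bundle.metadata, indent=2, default=str) + "\n", meta_path)
    written.append(meta_path)

    lines = ["loyscan analysis summary", "========================", ""]
    for stratum, calls in bundle.calls.items():
        counts = calls["label"].value_counts()
        lines.append(
            f"{stratum}: n={len(calls)}  "
            f"LOY={counts.get(LOY, 0)}  RETAINED={counts.get(RETAINED, 0)}  "
            f"UNCERTAIN={counts.get('UNCERTAIN', 0)}  "
            f"peaks=({calls['peak_low'].iloc[0]:.3f}, {calls['peak_high'].iloc[0]:.3f})"
        )
    for note in bundle.metadata.get("annotations", []):
        lines.append(f"note: {note}")
    summary_path = out / "summary.txt"
    _atomic_write("\n".join(lines) + "\n", summary_path)
    written.append(summary_path)
    return written
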