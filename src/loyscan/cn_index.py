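"""Arm- and chromosome-level copy-number indices from segmented data.

Converts SEG-style segmented copy-number profiles into length-weighted
average copy-number indices per chromosome arm, a purity-adjusted index over
the Y male-specific region (pseudoautosomal regions masked), and a total
autosomal aneuploidy index (sum over included arms of ``|2 - index|``).

All internal coordinates are 0-based half-open; SEG input is 1-based
inclusive and converted on read.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALUE_SCALES = ("log2ratio", "linear")

#: chromosome names accepted after normalization
CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

AUTOSOMES = tuple(str(i) for i in range(1, 23))

#: arms absent from SNP-array coverage and excluded from the aneuploidy sum
DEFAULT_EXCLUDED_ARMS = frozenset({"13p", "14p", "15p", "22p"})


class SegParseError(ValueError):
    """Raised when a SEG file cannot be parsed; message carries the line number."""


@dataclass(frozen=True, slots=True)
class SegmentRecord:
    """One copy-number segment of one sample (0-based half-open coordinates)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_markers: int | None
    value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment start must be < end, got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.value):
            raise ValueError(f"segment value must be finite, got {self.value}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class Arm:
    """A chromosome arm interval."""

    chromosome: str
    arm: str
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chromosome}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _normalize_chromosome(raw: str) -> str:
    name = str(raw).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name == "23":
        name = "X"
    elif name == "24":
        name = "Y"
    return name.upper() if name.lower() in ("x", "y") else name


def to_linear_cn(value: float, value_scale: str) -> float:
    """Convert a segment value to linear copy number (diploid = 2).

    ``log2ratio`` values are log2(CN / 2); ``linear`` passes through.
    """
    if value_scale == "log2ratio":
        return 2.0 * 2.0 ** value
    if value_scale == "linear":
        return float(value)
    raise ValueError(f"value_scale must be one of {VALUE_SCALES}, got {value_scale!r}")


def read_seg(path: str | Path, value_scale: str = "log2ratio") -> list[SegmentRecord]:
    """Read a SEG file (tab-separated, 1-based inclusive) into segment records.

    Expected columns: Sample, Chromosome, Start, End, Num_Probes, Segment_Mean
    (a header line is detected and skipped; the marker column may be blank).
    Values are stored as read — convert with :func:`to_linear_cn`.

    Raises
    ------
    SegParseError
        On unknown chromosome, start >= end, or non-numeric fields; the
        message names the offending 1-based line number.
    """
    if value_scale not in VALUE_SCALES:
        raise ValueError(f"value_scale must be one of {VALUE_SCALES}, got {value_scale!r}")
    path = Path(path)
    records: list[SegmentRecord] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SegParseError(f"{path}:{lineno}: expected 6 tab-separated columns")
            sample, chrom, start_s, end_s, markers_s, value_s = fields[:6]
            if lineno == 1 and not _is_number(start_s):
                continue  # header
            chrom = _normalize_chromosome(chrom)
            if chrom not in CHROMOSOMES:
                raise SegParseError(f"{path}:{lineno}: unknown chromosome {fields[1]!r}")
            try:
                start = int(float(start_s))
                end = int(float(end_s))
            except ValueError:
                raise SegParseError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start > end:
                raise SegParseError(f"{path}:{lineno}: start {start} > end {end}")
            if not _is_number(value_s):
                raise SegParseError(f"{path}:{lineno}: non-numeric segment value {value_s!r}")
            markers = int(float(markers_s)) if _is_number(markers_s) else None
            # 1-based inclusive -> 0-based half-open
            records.append(
                SegmentRecord(sample, chrom, start - 1, end, markers, float(value_s))
            )
    if not records:
        logger.warning("no segments read from %s", path)
    return records


def _is_number(text: str) -> bool:
    try:
        float(text)
    except (TypeError, ValueError):
        return False
    return True


def segments_by_sample(records: Iterable[SegmentRecord]) -> dict[str, list[SegmentRecord]]:
    """Group segment records by sample id, preserving order."""
    out: dict[str, list[SegmentRecord]] = {}
    for rec in records:
        out.setdefault(rec.sample_id, []).append(rec)
    return out


# ---------------------------------------------------------------------------
# Genome arm definitions


def _subtract_intervals(
    start: int, end: int, exclusions: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """[start, end) minus a set of exclusion intervals, as sorted kept pieces."""
    kept = [(start, end)]
    for ex_start, ex_end in exclusions:
        new: list[tuple[int, int]] = []
        for s, e in kept:
            if ex_end <= s or ex_start >= e:
                new.append((s, e))
                continue
            if s < ex_start:
                new.append((s, ex_start))
            if ex_end < e:
                new.append((ex_end, e))
        kept = new
    return kept


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


class GenomeArms:
    """Arm boundaries, exclusion intervals (PARs), and the excluded-arm set.

    Parameters
    ----------
    arms:
        Arm definitions ordered p before q within a chromosome.
    exclusions:
        Mapping of chromosome -> intervals masked out of both arm length and
        segment overlap (0-based half-open).
    excluded_arms:
        Arm names (e.g. ``"13p"``) skipped by the aneuploidy sum.
    """

    def __init__(
        self,
        arms: Sequence[Arm],
        exclusions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
        excluded_arms: frozenset[str] = DEFAULT_EXCLUDED_ARMS,
    ) -> None:
        self.arms = list(arms)
        self.exclusions = {k: list(v) for k, v in (exclusions or {}).items()}
        self.excluded_arms = frozenset(excluded_arms)
        self._by_name = {arm.name: arm for arm in self.arms}

    @classmethod
    def grch37(cls, exclude_21p: bool = False) -> "GenomeArms":
        """Load the packaged GRCh37/hg19 arm table and PAR intervals.

        ``exclude_21p=True`` additionally drops 21p from the aneuploidy sum
        (21 is acrocentric but 21p is covered by the arrays).
        """
        data = resources.files("loyscan.data")
        arm_df = pd.read_csv(data / "grch37_arms.tsv", sep="\t", dtype={"chromosome": str})
        par_df = pd.read_csv(data / "par_grch37.tsv", sep="\t", dtype={"chromosome": str})
        arms = [
            Arm(row.chromosome, row.arm, int(row.start), int(row.end))
            for row in arm_df.itertuples()
        ]
        exclusions: dict[str, list[tuple[int, int]]] = {}
        for row in par_df.itertuples():
            exclusions.setdefault(row.chromosome, []).append((int(row.start), int(row.end)))
        excluded = set(DEFAULT_EXCLUDED_ARMS)
        if exclude_21p:
            excluded.add("21p")
        return cls(arms, exclusions, frozenset(excluded))

    def arm(self, name: str) -> Arm:
        return self._by_name[name]

    def arms_of(self, chromosome: str) -> list[Arm]:
        return [a for a in self.arms if a.chromosome == chromosome]

    def autosomal_arms(self, include_excluded: bool = False) -> list[Arm]:
        arms = [a for a in self.arms if a.chromosome in AUTOSOMES]
        if not include_excluded:
            arms = [a for a in arms if a.name not in self.excluded_arms]
        return arms

    def masked_intervals(self, arm: Arm) -> list[tuple[int, int]]:
        """Arm interval minus any exclusion intervals on its chromosome."""
        return _subtract_intervals(
            arm.start, arm.end, self.exclusions.get(arm.chromosome, ())
        )

    def masked_length(self, arm: Arm) -> int:
        return sum(e - s for s, e in self.masked_intervals(arm))


# ---------------------------------------------------------------------------
# Indices


def arm_index(
    segments: Iterable[SegmentRecord],
    arm: Arm,
    exclusions: Sequence[tuple[int, int]] = (),
) -> tuple[float, float]:
    """Length-weighted average linear CN of one sample over one arm.

    Segments must already be on the linear CN scale. Exclusion intervals are
    removed from both the arm length and the segment overlaps.

    Returns ``(index, covered_fraction)``; the index is NaN when nothing
    overlaps the masked arm.
    """
    kept = _subtract_intervals(arm.start, arm.end, exclusions)
    masked_length = sum(e - s for s, e in kept)
    if masked_length == 0:
        return float("nan"), 0.0
    weighted = 0.0
    covered = 0
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        for s, e in kept:
            ov = _overlap(seg.start, seg.end, s, e)
            if ov:
                weighted += ov * seg.value
                covered += ov
    if covered == 0:
        return float("nan"), 0.0
    return weighted / covered, covered / masked_length


def purity_adjust(observed_index: float, purity: float | None, normal_cn: float):
    """Invert the two-component purity mixture to recover tumor copy number.

    ``observed = p * tumor + (1 - p) * normal`` solved for tumor and floored
    at zero. A missing purity returns the observed value unchanged (callers
    flag the sample as unadjusted).
    """
    if purity is None or (np.isscalar(purity) and not math.isfinite(purity)):
        return observed_index
    if purity == 0:
        raise ValueError("purity must be in (0, 1], got 0")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    adjusted = (np.asarray(observed_index, dtype=float) - (1.0 - purity) * normal_cn) / purity
    adjusted = np.maximum(adjusted, 0.0)
    return float(adjusted) if np.ndim(observed_index) == 0 else adjusted


def y_index(
    segments: Iterable[SegmentRecord],
    genome: GenomeArms,
    purity: float | None = None,
) -> float:
    """Purity-adjusted average linear CN over the Y male-specific region.

    The pseudoautosomal regions are masked; adjustment uses a normal copy
    number of 1 (one Y per normal male cell). NaN when no Y coverage.
    """
    segs = [s for s in segments if s.chromosome == "Y"]
    weighted = 0.0
    covered = 0
    for arm in genome.arms_of("Y"):
        for s, e in genome.masked_intervals(arm):
            for seg in segs:
                ov = _overlap(seg.start, seg.end, s, e)
                if ov:
                    weighted += ov * seg.value
                    covered += ov
    if covered == 0:
        logger.warning("no Y coverage for sample; Y index absent")
        return float("nan")
    return purity_adjust(weighted / covered, purity, normal_cn=1.0)


def aneuploidy_index(
    arm_indices: Mapping[str, float],
    genome: GenomeArms,
    purity: float | None = None,
) -> float:
    """Total autosomal aneuploidy: sum over included arms of ``|2 - index|``.

    ``arm_indices`` maps arm name -> observed (unadjusted) linear CN index;
    each arm is purity-adjusted with a normal CN of 2 before summing. Arms
    that are absent or NaN are skipped with a logged count.
    """
    total = 0.0
    skipped = 0
    for arm in genome.autosomal_arms():
        value = arm_indices.get(arm.name, float("nan"))
        if value is None or not math.isfinite(value):
            skipped += 1
            continue
        total += abs(2.0 - purity_adjust(value, purity, normal_cn=2.0))
    if skipped:
        logger.debug("aneuploidy_index: skipped %d uncovered arms", skipped)
    return total


@dataclass
class ArmIndexMatrix:
    """Sample x arm observed linear CN indices plus covered fractions."""

    index: pd.DataFrame
    covered_fraction: pd.DataFrame
    purity_adjusted: bool = False
    low_confidence_threshold: float = 0.5

    def low_confidence(self) -> pd.DataFrame:
        """Boolean mask of cells covered below the confidence threshold."""
        return self.covered_fraction < self.low_confidence_threshold


def arm_index_matrix(
    per_sample: Mapping[str, Sequence[SegmentRecord]],
    genome: GenomeArms,
) -> ArmIndexMatrix:
    """Compute observed (unadjusted) arm indices for every sample and arm."""
    arm_names = [a.name for a in genome.arms]
    rows = {}
    cov_rows = {}
    for sample, segs in per_sample.items():
        values = {}
        covs = {}
        for arm in genome.arms:
            idx, cov = arm_index(segs, arm, genome.exclusions.get(arm.chromosome, ()))
            values[arm.name] = idx
            covs[arm.name] = cov
        rows[sample] = values
        cov_rows[sample] = covs
    index = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=arm_names)
    covered = pd.DataFrame.from_dict(cov_rows, orient="index").reindex(columns=arm_names)
    index.index.name = covered.index.name = "sample_id"
    return ArmIndexMatrix(index=index, covered_fraction=covered)


def linearize(records: Iterable[SegmentRecord], value_scale: str) -> list[SegmentRecord]:
    """Return segment records with values converted to the linear CN scale."""
    if value_scale == "linear":
        return list(records)
    return [
        SegmentRecord(
            r.sample_id, r.chromosome, r.start, r.end, r.n_markers,
            to_linear_cn(r.value, value_scale),
        )
        for r in records
    ]


def sample_indices(
    per_sample: Mapping[str, Sequence[SegmentRecord]],
    genome: GenomeArms,
    purity: Mapping[str, float] | None = None,
    sex: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample Y index and total autosomal aneuploidy index.

    Parameters
    ----------
    per_sample:
        Segments (linear CN scale) grouped by sample.
    purity:
        Sample -> tumor purity in (0, 1]; missing samples are left
        unadjusted and flagged.
    sex:
        Sample -> ``"male"``/``"female"``; the Y index is only computed for
        males (or for all samples when sex is unknown).

    Returns a frame indexed by sample with columns ``y_index``,
    ``aneuploidy_index``, ``purity``, ``purity_adjusted``.
    """
    purity = purity or {}
    records = []
    for sample, segs in per_sample.items():
        p = purity.get(sample)
        if p is not None and not (isinstance(p, float) and math.isnan(p)):
            p = float(p)
        else:
            p = None
        sample_sex = (sex or {}).get(sample)
        arm_values = {}
        for arm in genome.autosomal_arms():
            idx, _cov = arm_index(segs, arm, genome.exclusions.get(arm.chromosome, ()))
            arm_values[arm.name] = idx
        aneu = aneuploidy_index(arm_values, genome, purity=p)
        if sample_sex == "female":
            y_val = float("nan")
        else:
            y_val = y_index(segs, genome, purity=p)
        records.append(
            {
                "sample_id": sample,
                "y_index": y_val,
                "aneuploidy_index": aneu,
                "purity": p if p is not None else float("nan"),
                "purity_adjusted": p is not None,
            }
        )
    return pd.DataFrame.from_records(records).set_index("sample_id")
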