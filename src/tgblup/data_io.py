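"""Phenotype/genotype file handling, marker quality control, and run outputs.

Phenotype files are plain CSV with columns ``env,line,rep,score`` where
``score`` is an ordinal category in ``1..C``.  Genotype files are a
line x marker matrix of additive allele counts (0/1/2, missing as blank/NA),
either CSV with a marker-id header and a line-id first column, or a
PLINK-RAW-style whitespace table (``FID IID PAT MAT SEX PHENOTYPE SNP...``)
of which only the additive-count columns are used.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tgblup")

PHENOTYPE_COLUMNS = ("env", "line", "rep", "score")

__all__ = [
    "PhenotypeTable",
    "RawGenotypes",
    "QCReport",
    "RunOutputs",
    "read_phenotypes",
    "read_genotypes",
    "qc_markers",
    "write_run_outputs",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhenotypeTable:
    """Ordinal phenotype records y_ijk over environments i, lines j, replicates k.

    ``records`` keeps user ids verbatim; 0-based integer codes for
    environments and lines (in first-appearance order) are derived for the
    numerical machinery.
    """

    records: pd.DataFrame
    n_categories: int

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        if self.n_categories < 2:
            raise ValueError("at least two ordinal categories are required")
        self.records = self.records.reset_index(drop=True)
        score = self.records["score"].to_numpy()
        if not np.issubdtype(np.asarray(score).dtype, np.number) or np.any(score != np.floor(score)):
            raise ValueError("scores must be integers")
        self.score = score.astype(int)
        if self.score.min() < 1 or self.score.max() > self.n_categories:
            bad = int(np.argmax((self.score < 1) | (self.score > self.n_categories)))
            raise ValueError(
                f"score {self.score[bad]} at row {bad} outside 1..{self.n_categories}"
            )
        dup = self.records.duplicated(subset=["env", "line", "rep"])
        if dup.any():
            raise ValueError(
                f"duplicate (env, line, rep) triple at row {int(np.argmax(dup.to_numpy()))}"
            )
        self.env_ids = tuple(pd.unique(self.records["env"]))
        self.line_ids = tuple(pd.unique(self.records["line"]))
        env_pos = {e: i for i, e in enumerate(self.env_ids)}
        line_pos = {l: j for j, l in enumerate(self.line_ids)}
        self.env_index = self.records["env"].map(env_pos).to_numpy(dtype=int)
        self.line_index = self.records["line"].map(line_pos).to_numpy(dtype=int)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_environments(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def cell_counts(self) -> pd.Series:
        """Replication counts N_ij per (environment, line) cell."""
        return self.records.groupby(["env", "line"], sort=False).size()

    def subset(self, rows: Sequence[int]) -> "PhenotypeTable":
        """A new table containing the given record rows (same C)."""
        return PhenotypeTable(self.records.iloc[list(rows)].copy(), self.n_categories)


@dataclasses.dataclass
class RawGenotypes:
    """Line x marker additive genotype calls; NaN marks missing calls.

    After :func:`qc_markers` imputation, calls may be fractional (2*p_m).
    """

    line_ids: tuple
    marker_ids: tuple
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.calls).sum())


@dataclasses.dataclass
class QCReport:
    """Outcome of marker quality control."""

    n_input_markers: int
    removed_missingness: tuple
    removed_maf: tuple
    retained: tuple
    line_call_rate: pd.Series
    allele_frequencies: pd.Series

    def __post_init__(self) -> None:
        n_removed = len(self.removed_missingness) + len(self.removed_maf)
        if n_removed + len(self.retained) != self.n_input_markers:
            raise ValueError("QC accounting error: removed + retained != input markers")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_phenotypes(path, category_count: Optional[int] = None) -> PhenotypeTable:
    """Read and validate an ordinal phenotype CSV.

    If ``category_count`` is omitted, C is the maximum observed score.
    Errors name the offending data row (0-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    numeric = pd.to_numeric(df["score"], errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"{path}: non-integer score {df['score'].iloc[row]!r} at row {row}")
    df["score"] = numeric.astype(int)
    c = int(category_count) if category_count is not None else int(df["score"].max())
    if (df["score"] < 1).any() or (df["score"] > c).any():
        out = (df["score"] < 1) | (df["score"] > c)
        row = int(np.argmax(out.to_numpy()))
        raise ValueError(f"{path}: score {df['score'].iloc[row]} at row {row} outside 1..{c}")
    dup = df.duplicated(subset=["env", "line", "rep"])
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise ValueError(f"{path}: duplicate (env, line, rep) at row {row}")
    table = PhenotypeTable(df, c)
    logger.info(
        "read %d phenotype records (%d environments, %d lines, C=%d) from %s",
        table.n_records, table.n_environments, table.n_lines, c, path,
    )
    return table


_MISSING_TOKENS = {"", "NA", "N/A", "NAN", ".", "-9"}


def _parse_call(token: str, where: str) -> float:
    token = token.strip()
    if token.upper() in _MISSING_TOKENS:
        return math.nan
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"genotype call {token!r} at {where} is not in {{0,1,2,missing}}")
    if value not in (0.0, 1.0, 2.0):
        raise ValueError(f"genotype call {token!r} at {where} is not in {{0,1,2,missing}}")
    return value


def read_genotypes(path) -> RawGenotypes:
    """Read a line x marker genotype matrix (CSV or PLINK-RAW-style text).

    Input order of lines and markers is preserved.  Ragged rows and calls
    outside {0,1,2,missing} raise ``ValueError``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        fh.seek(0)
        if "," in first:
            rows = list(csv.reader(fh))
        else:
            rows = [line.split() for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least one genotype row")
    header = rows[0]
    plink_raw = [h.upper() for h in header[:2]] == ["FID", "IID"]
    skip = 6 if plink_raw else 1
    id_col = 1 if plink_raw else 0
    marker_ids = tuple(header[skip:])
    if not marker_ids:
        raise ValueError(f"{path}: no marker columns found")
    width = len(header)
    line_ids = []
    calls = np.empty((len(rows) - 1, len(marker_ids)))
    for r, row in enumerate(rows[1:]):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {r} (expected {width} fields, got {len(row)})")
        line_ids.append(row[id_col])
        for m, token in enumerate(row[skip:]):
            calls[r, m] = _parse_call(token, f"row {r}, marker {marker_ids[m]}")
    geno = RawGenotypes(tuple(line_ids), marker_ids, calls)
    logger.info(
        "read genotypes for %d lines x %d markers (%d missing calls) from %s",
        geno.n_lines, geno.n_markers, geno.n_missing, path,
    )
    return geno


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_markers(
    geno: RawGenotypes,
    max_missing_fraction: float = 0.10,
    min_maf_exclusive: float = 0.05,
) -> tuple[RawGenotypes, QCReport]:
    """Apply the marker filters and impute the remaining missing calls.

    Markers with a missing fraction strictly above ``max_missing_fraction``
    are removed first; among the survivors, markers with minor allele
    frequency less than *or equal to* ``min_maf_exclusive`` are removed
    (the boundary is excluded).  Frequencies p_m = mean(x)/2 are computed on
    non-missing calls, and residual missing calls are imputed to 2*p_m so the
    imputation leaves p_m unchanged.
    """
    if geno.n_markers == 0 or geno.n_lines == 0:
        raise ValueError("empty genotype matrix")
    calls = geno.calls
    miss = np.isnan(calls)
    miss_frac = miss.mean(axis=0)
    keep_missing = miss_frac <= max_missing_fraction
    removed_missingness = tuple(
        m for m, keep in zip(geno.marker_ids, keep_missing) if not keep
    )

    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_maf = keep_missing & (maf > min_maf_exclusive)
    removed_maf = tuple(
        m for m, km, k in zip(geno.marker_ids, keep_missing, keep_maf) if km and not k
    )
    retained = tuple(m for m, k in zip(geno.marker_ids, keep_maf) if k)
    if not retained:
        raise ValueError(
            "all markers removed by QC; review max_missing_fraction/min_maf_exclusive"
        )

    kept = calls[:, keep_maf].copy()
    p_kept = p[keep_maf]
    nan_rows, nan_cols = np.nonzero(np.isnan(kept))
    kept[nan_rows, nan_cols] = 2.0 * p_kept[nan_cols]

    call_rate = pd.Series(1.0 - miss.mean(axis=1), index=list(geno.line_ids), name="call_rate")
    report = QCReport(
        n_input_markers=geno.n_markers,
        removed_missingness=removed_missingness,
        removed_maf=removed_maf,
        retained=retained,
        line_call_rate=call_rate,
        allele_frequencies=pd.Series(p_kept, index=list(retained), name="p"),
    )
    logger.info(
        "marker QC: %d input, %d removed (>%.0f%% missing), %d removed (MAF<=%.3g), %d retained",
        geno.n_markers, len(removed_missingness), 100 * max_missing_fraction,
        len(removed_maf), len(retained),
    )
    return RawGenotypes(geno.line_ids, retained, kept), report


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunOutputs:
    """Everything a fit/CV run writes to disk."""

    posterior_summary: pd.DataFrame
    predictions: pd.DataFrame
    cv_scores: pd.DataFrame
    config: Mapping


def write_run_outputs(results: RunOutputs, out_dir) -> list[Path]:
    """Write posterior summaries, predictions, CV scores and the run config.

    Returns the manifest of written files.  Identical inputs produce
    byte-identical files, and all CSVs round-trip exactly (floats are written
    with shortest-round-trip repr).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    manifest = []
    for name, frame in (
        ("posterior_summary.csv", results.posterior_summary),
        ("predictions.csv", results.predictions),
        ("cv_scores.csv", results.cv_scores),
    ):
        target = out_dir / name
        frame.to_csv(target, index=False)
        manifest.append(target)
    config_path = out_dir / "run_config.json"
    config_path.write_text(json.dumps(dict(results.config), indent=2, sort_keys=True, default=str))
    manifest.append(config_path)
    logger.info("wrote %d run output files to %s", len(manifest), out_dir)
    return manifest
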