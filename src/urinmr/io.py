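"""Readers and writers for every on-disk artifact the pipeline touches.

Formats are deliberately plain text: two-column ASCII for spectra
(whitespace- or comma-separated, ``#`` comments allowed, the dialect of
common Topspin ``convbin2asc``-style exports), CSV for clinical and
feature tables, JSON for the pathway library.  Every reader validates;
every reader/writer pair is an identity on valid files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, validate_record

logger = logging.getLogger(__name__)

#: significant digits used when serializing floating-point numbers
FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """A file violated the expected on-disk format or an invariant."""


@dataclass
class Spectrum:
    """One sample's 1D NMR spectrum: ppm axis (descending) + intensities."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise FormatError("ppm and intensity must be 1-D and equal length")
        if not np.all(np.isfinite(self.intensity)) or not np.all(np.isfinite(self.ppm)):
            raise FormatError("spectrum contains non-finite values")
        if len(self.ppm) >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise FormatError("ppm axis must be strictly monotone descending")

    def __len__(self) -> int:
        return len(self.ppm)


@dataclass
class FeatureMatrix:
    """Samples x bins intensity table plus the bin manifest.

    ``values`` is indexed by sample id with one column per non-excluded
    bin (column labels are the bin ids of ``bins``).  ``bins`` carries
    the full manifest — left/right/center ppm, the excluded flag and an
    optional metabolite label — including bins that were excluded and
    therefore have no column in ``values``.
    """

    values: pd.DataFrame
    bins: pd.DataFrame  # columns: left, right, center, excluded, label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicated sample ids: {dupes}")
        req = {"left", "right", "center", "excluded", "label"}
        missing = req - set(self.bins.columns)
        if missing:
            raise FormatError(f"bin manifest missing columns: {sorted(missing)}")
        if not np.all(self.bins["left"].to_numpy() > self.bins["right"].to_numpy()):
            raise FormatError("each bin needs left ppm > right ppm")
        # bins are stored left-to-right in descending ppm; check no overlap
        b = self.bins.sort_values("left", ascending=False)
        lefts, rights = b["left"].to_numpy(), b["right"].to_numpy()
        if np.any(lefts[1:] - rights[:-1] > 1e-9):
            raise FormatError("bins overlap")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise FormatError("feature matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def active_bins(self) -> pd.DataFrame:
        return self.bins.loc[~self.bins["excluded"]]


@dataclass
class Pathway:
    id: str
    name: str
    compounds: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.compounds) != len({c.lower() for c in self.compounds}):
            raise FormatError(f"pathway {self.id}: duplicate compound ids")
        for a, b in self.edges:
            if a not in self.compounds or b not in self.compounds:
                raise FormatError(
                    f"pathway {self.id}: edge ({a}, {b}) references unknown compound"
                )


@dataclass
class PathwayLibrary:
    pathways: list[Pathway]
    synonyms: dict[str, str] = field(default_factory=dict)

    def universe(self) -> set[str]:
        """All unique compound ids across the library (lower-cased)."""
        out: set[str] = set()
        for pw in self.pathways:
            out |= {c.lower() for c in pw.compounds}
        return out


# ---------------------------------------------------------------------------
# spectra

_NUM_SPLIT = re.compile(r"[,\s]+")


def read_spectrum(path: str | Path) -> Spectrum:
    """Parse a two-column ASCII spectrum (ppm, intensity).

    Lines starting with ``#`` and blank lines are ignored.  An
    ascending ppm axis on disk is accepted and reversed (with a log
    note); anything non-monotone is rejected.
    """
    path = Path(path)
    ppm, intensity = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _NUM_SPLIT.split(line) if p]
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two numeric fields, got {len(parts)}"
                )
            try:
                ppm.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
    x = np.array(ppm)
    y = np.array(intensity)
    if len(x) >= 2 and np.all(np.diff(x) > 0):
        logger.info("%s: ascending ppm axis on disk; reversing to descending", path)
        x, y = x[::-1], y[::-1]
    return Spectrum(ppm=x, intensity=y)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# ppm intensity\n")
        for p, v in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{FLOAT_FMT % p} {FLOAT_FMT % v}\n")


# ---------------------------------------------------------------------------
# clinical table

CLINICAL_COLUMNS = [
    "subject_id",
    "stroke_type",
    "sex",
    "age",
    "acute_day",
    "chronic_day",
    "nihss_initial",
    "fim_initial",
    "fim_6mo",
    "cmsa_hand_initial",
    "cmsa_hand_6mo",
    "cmsa_arm_initial",
    "cmsa_arm_6mo",
]


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical-scores CSV into validated records.

    Empty cells and the literal ``NaN`` become explicit missing values.
    Score ranges are validated (NIHSS 0–42, FIM 18–126, CMSA 1–7); an
    out-of-range value raises a :class:`FormatError` naming row and
    column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing_cols = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for i, row in df.iterrows():
        rec = ClinicalRecord(
            subject_id=str(row["subject_id"]),
            stroke_type=str(row["stroke_type"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            acute_day=float(row["acute_day"]),
            chronic_day=float(row["chronic_day"]),
            nihss_initial=_opt(row["nihss_initial"]),
            fim_initial=_opt(row["fim_initial"]),
            fim_6mo=_opt(row["fim_6mo"]),
            cmsa_hand_initial=_opt(row["cmsa_hand_initial"]),
            cmsa_hand_6mo=_opt(row["cmsa_hand_6mo"]),
            cmsa_arm_initial=_opt(row["cmsa_arm_initial"]),
            cmsa_arm_6mo=_opt(row["cmsa_arm_6mo"]),
        )
        try:
            validate_record(rec)
        except ValueError as exc:
            raise FormatError(f"{path}: row {i} ({rec.subject_id}): {exc}") from exc
        records.append(rec)
    logger.info("%s: read %d clinical records", path, len(records))
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {col: getattr(r, col) for col in CLINICAL_COLUMNS} for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False, na_rep="NaN")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().lower() in {"", "nan"}:
        return None
    return float(value)


# ---------------------------------------------------------------------------
# feature matrix

_BIN_HEADER = re.compile(
    r"^(?P<label>[^@]*)@(?P<center>[^\[]+)\[(?P<left>[^:]+):(?P<right>[^\]]+)\]$"
)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Serialize values + bin metadata to a single CSV.

    Column headers encode label, center and edges as
    ``label@center[left:right]``; excluded bins live only in the
    companion manifest written by the pipeline, so a round trip
    preserves the active part of the matrix exactly.
    """
    active = matrix.active_bins()
    headers = [
        f"{row.label if row.label else ''}@{FLOAT_FMT % row.center}"
        f"[{FLOAT_FMT % row.left}:{FLOAT_FMT % row.right}]"
        for row in active.itertuples()
    ]
    out = matrix.values.copy()
    out.columns = headers
    out.index.name = "sample_id"
    out.to_csv(path, float_format=FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    bins = []
    for col in df.columns:
        m = _BIN_HEADER.match(col)
        if m is None:
            raise FormatError(f"{path}: malformed bin header {col!r}")
        bins.append(
            {
                "label": m["label"] or None,
                "center": float(m["center"]),
                "left": float(m["left"]),
                "right": float(m["right"]),
                "excluded": False,
            }
        )
    bins_df = pd.DataFrame(bins, columns=["left", "right", "center", "excluded", "label"])
    values = df.copy()
    values.columns = bins_df.index
    return FeatureMatrix(values=values, bins=bins_df)


def write_bin_manifest(bins: pd.DataFrame, path: str | Path) -> None:
    bins.to_csv(path, index_label="bin_id", float_format=FLOAT_FMT)


def read_bin_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="bin_id")


# ---------------------------------------------------------------------------
# pathway library

def read_pathway_library(path: str | Path) -> PathwayLibrary:
    with Path(path).open() as fh:
        raw = json.load(fh)
    pathways = [
        Pathway(
            id=p["id"],
            name=p["name"],
            compounds=set(p["compounds"]),
            edges=[tuple(e) for e in p.get("edges", [])],
        )
        for p in raw["pathways"]
    ]
    return PathwayLibrary(pathways=pathways, synonyms=raw.get("synonyms", {}))


def write_pathway_library(library: PathwayLibrary, path: str | Path) -> None:
    raw = {
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "compounds": sorted(p.compounds),
                "edges": [list(e) for e in p.edges],
            }
            for p in library.pathways
        ],
        "synonyms": library.synonyms,
    }
    with Path(path).open("w") as fh:
        json.dump(raw, fh, indent=2, sort_keys=True)
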