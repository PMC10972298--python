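"""Packaged reference fixtures: clinical table, shift assignments, pathway library."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io
from .clinical import ClinicalRecord


def _data_path(name: str):
    return resources.files("urinmr.data") / name


def load_clinical_cohort() -> list[ClinicalRecord]:
    """The packaged 10-subject paired stroke cohort (clinical scores + demographics)."""
    with resources.as_file(_data_path("stroke_clinical.csv")) as path:
        return io.read_clinical_table(path)


def load_shift_assignments() -> pd.DataFrame:
    """ppm -> metabolite-name lookup for labelling bins (columns: ppm, metabolite)."""
    with resources.as_file(_data_path("shift_assignments.csv")) as path:
        return pd.read_csv(path)


def load_pathway_library() -> io.PathwayLibrary:
    """Small synthetic pathway library bundled for over-representation analysis."""
    with resources.as_file(_data_path("pathways.json")) as path:
        return io.read_pathway_library(path)


def label_bins(bins: pd.DataFrame, tolerance: float = 0.01) -> pd.DataFrame:
    """Attach metabolite labels to bins whose center sits within ``tolerance`` ppm
    of a known chemical shift.  Returns a copy; unmatched bins keep label None."""
    lookup = load_shift_assignments()
    out = bins.copy()
    labels = []
    for center in out["center"]:
        dist = (lookup["ppm"] - center).abs()
        idx = dist.idxmin()
        labels.append(lookup.loc[idx, "metabolite"] if dist[idx] <= tolerance else None)
    out["label"] = labels
    return out
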