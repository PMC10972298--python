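"""Synthetic paired urine-NMR cohorts with a known ground truth.

The generator emulates the statistical structure of a paired
acute/chronic urinary metabolomics study: Lorentzian metabolite peaks
at literature chemical shifts with per-sample ppm jitter, a smooth
baseline, additive Gaussian noise, broad water/urea humps, per-subject
log-normal concentrations with a per-sample dilution factor, planted
chronic-vs-acute fold changes on a subset of metabolites, additive
age/sex confounds on log-concentration, and clinical recovery scores
monotonically linked to a designated metabolite's percent change.
Everything is reproducible from a single seed and the planted truth is
returned alongside the data, so each downstream stage has a
recoverable answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, percent_difference
from .io import Spectrum

# Chemical shifts (ppm) of urinary metabolites used as library anchors.
NAMED_SHIFTS: dict[str, list[float]] = {
    "pseudouridine": [4.299, 4.290],
    "4-hydroxy-3-methoxymandelate": [3.887],
    "inosine": [8.219],
    "homovanillate": [3.874],
    "adenosine": [4.315],
    "2-aminobutyrate": [0.982],
    "ethanolamine": [3.156],
    "deoxyinosine": [6.494],
    "phenylacetic acid": [7.328, 7.312],
    "acetylcholine": [2.157],
    "l-tyrosine": [6.907],
    "anserine": [7.138],
    "alanine": [1.493],
}

#: default chronic-vs-acute log2 fold changes planted on the biomarker panel
DEFAULT_EFFECTS: dict[str, float] = {
    "pseudouridine": -1.0,
    "4-hydroxy-3-methoxymandelate": 0.9,
    "inosine": -0.9,
    "homovanillate": 0.8,
    "adenosine": -0.8,
    "2-aminobutyrate": -0.7,
    "ethanolamine": 0.7,
    "deoxyinosine": 0.7,
}

WATER_REGION = (4.70, 5.00)
UREA_REGION = (5.40, 6.00)


@dataclass
class MetabolitePeak:
    center: float  # ppm
    height_weight: float  # peak height per unit concentration
    linewidth: float  # Lorentzian half width at half maximum, ppm


@dataclass
class MetaboliteEntry:
    name: str
    peaks: list[MetabolitePeak]


@dataclass
class MetaboliteLibrary:
    entries: list[MetaboliteEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.peaks:
                raise ValueError(f"metabolite {e.name} has no peaks")
            for p in e.peaks:
                if p.linewidth <= 0:
                    raise ValueError(f"metabolite {e.name}: linewidth must be > 0")

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def get(self, name: str) -> MetaboliteEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"unknown metabolite: {name}")


def default_library(
    n_metabolites: int = 13,
    seed: int = 0,
    window: tuple[float, float] = (0.5, 9.4),
    linewidth: float = 0.015,
) -> MetaboliteLibrary:
    """Library with the named urinary metabolites first, then random fillers.

    The first ``min(n, 13)`` entries are the named metabolites at their
    literature shifts; beyond 13, filler singlets are placed uniformly
    in the window (outside the water/urea regions), deterministically
    from ``seed``.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for name, shifts in list(NAMED_SHIFTS.items())[:n_metabolites]:
        peaks = [
            MetabolitePeak(center=s, height_weight=1.0 / len(shifts), linewidth=linewidth)
            for s in shifts
        ]
        entries.append(MetaboliteEntry(name=name, peaks=peaks))
    i = 0
    while len(entries) < n_metabolites:
        c = float(rng.uniform(*window))
        if WATER_REGION[0] - 0.05 < c < WATER_REGION[1] + 0.05:
            continue
        if UREA_REGION[0] - 0.05 < c < UREA_REGION[1] + 0.05:
            continue
        entries.append(
            MetaboliteEntry(
                name=f"metab_{i:03d}",
                peaks=[MetabolitePeak(center=c, height_weight=float(rng.uniform(0.3, 1.0)),
                                      linewidth=linewidth)],
            )
        )
        i += 1
    return MetaboliteLibrary(entries=entries)


def lorentzian(x: np.ndarray, center: float, height: float, hwhm: float) -> np.ndarray:
    """Lorentzian lineshape with apex ``height``; area = height * pi * hwhm."""
    return height / (1.0 + ((x - center) / hwhm) ** 2)


def simulate_spectrum(
    concentrations: Mapping[str, float],
    library: MetaboliteLibrary,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    baseline_amplitude: float = 0.0,
    window: tuple[float, float] = (-0.2, 9.5),
    points: int = 4096,
    seed: int | np.random.Generator = 0,
    tsp_height: float = 0.0,
    tsp_offset: float = 0.0,
    water_height: float = 0.0,
    urea_height: float = 0.0,
) -> Spectrum:
    """One spectrum: sum of jittered Lorentzians + baseline + noise.

    The ppm grid is uniform and descending over ``window``.  Optional
    extras: a TSP reference singlet near ``tsp_offset`` ppm and broad
    water/urea humps (so referencing and region exclusion have
    something real to act on).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ppm = np.linspace(window[1], window[0], points)
    y = np.zeros(points)
    for name, conc in concentrations.items():
        entry = library.get(name)
        for pk in entry.peaks:
            jitter = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
            y += lorentzian(ppm, pk.center + jitter, conc * pk.height_weight, pk.linewidth)
    if tsp_height > 0:
        y += lorentzian(ppm, tsp_offset, tsp_height, 0.01)
    if water_height > 0:
        y += lorentzian(ppm, np.mean(WATER_REGION), water_height, 0.12)
    if urea_height > 0:
        y += lorentzian(ppm, np.mean(UREA_REGION), urea_height, 0.20)
    if baseline_amplitude != 0.0:
        span = window[1] - window[0]
        y += baseline_amplitude * (0.5 + 0.5 * np.sin(2 * np.pi * (ppm - window[0]) / span))
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=points)
    return Spectrum(ppm=ppm, intensity=y)


@dataclass
class ClinicalLink:
    """Monotone link from a metabolite's percent change to score improvements."""

    metabolite: str = "pseudouridine"
    slope: float = 0.08  # CMSA-hand points per percent metabolite change
    noise_sd: float = 0.15
    base: float = 6.0  # improvement at zero percent change (before clipping)


@dataclass
class CohortConfig:
    n_subjects: int = 10
    window: tuple[float, float] = (-0.2, 9.5)
    points: int = 4096
    effect_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    confound_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"l-tyrosine": (0.012, 0.25), "alanine": (-0.010, -0.20)}
    )
    jitter_sd: float = 0.002
    noise_sd: float = 0.004
    baseline_amplitude: float = 0.01
    subject_sigma: float = 0.35  # log-normal between-subject concentration spread
    fc_noise_sd: float = 0.2  # log-normal within-subject chronic noise
    dilution_sd: float = 0.3  # per-sample log-normal dilution factor
    tsp_height: float = 3.0
    water_height: float = 8.0
    urea_height: float = 4.0
    clinical_link: ClinicalLink = field(default_factory=ClinicalLink)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.points < 256:
            raise ValueError("points must be >= 256")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth: what a correct analysis should recover."""

    fold_changes: dict[str, float]
    informative: dict[str, bool]
    confound_coeffs: dict[str, tuple[float, float]]
    clinical_link: ClinicalLink
    concentrations: pd.DataFrame  # samples x metabolites, pre-dilution
    dilutions: pd.Series  # per-sample dilution factor
    metabolite_pct_diff: pd.DataFrame  # subjects x metabolites, Eq.-style percent change

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_changes": self.fold_changes,
            "informative": self.informative,
            "confound_coeffs": {k: list(v) for k, v in self.confound_coeffs.items()},
            "clinical_link": asdict(self.clinical_link),
            "concentrations": self.concentrations.round(12).to_dict(orient="index"),
            "dilutions": self.dilutions.round(12).to_dict(),
            "metabolite_pct_diff": self.metabolite_pct_diff.round(12).to_dict(orient="index"),
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class SimulatedCohort:
    spectra: dict[str, Spectrum]
    metadata: pd.DataFrame  # index sample_id: subject_id, phase, age, sex, collection_day
    clinical: list[ClinicalRecord]
    truth: CohortTruth


def _clip_round(x: float, lo: float, hi: float) -> float:
    return float(np.clip(np.round(x), lo, hi))


def simulate_cohort(config: CohortConfig, library: MetaboliteLibrary) -> SimulatedCohort:
    """Generate a full paired cohort (2 spectra per subject) plus its truth.

    Acute log-concentrations are per-subject log-normal draws plus
    additive age/sex confound terms; chronic concentrations multiply
    the acute ones by ``2**fold_change`` and a log-normal biological
    noise term.  A per-sample dilution factor scales whole spectra (to
    be removed by total-metabolome normalization downstream).  Clinical
    improvements follow the designated metabolite's percent change via
    ``ClinicalLink`` and are clipped/rounded to valid integer scores.
    """
    names = library.names()
    unknown = set(config.effect_table) - set(names)
    if unknown:
        raise ValueError(f"effect_table references unknown metabolites: {sorted(unknown)}")
    unknown_conf = set(config.confound_coeffs) - set(names)
    if unknown_conf:
        raise ValueError(
            f"confound_coeffs reference unknown metabolites: {sorted(unknown_conf)}"
        )
    link = config.clinical_link
    if link.metabolite not in names:
        raise ValueError(f"clinical_link metabolite {link.metabolite!r} not in library")

    ss = np.random.SeedSequence(config.seed)
    rng_conc, rng_demo, rng_clin, rng_spec = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n, p = config.n_subjects, len(names)
    subjects = [f"S{i + 1:02d}" for i in range(n)]

    ages = rng_demo.integers(38, 82, size=n).astype(float)
    sexes = (rng_demo.random(n) < 0.25).astype(int)  # 1 = female, minority as in stroke units
    acute_days = rng_demo.integers(2, 12, size=n).astype(float)
    chronic_days = rng_demo.integers(170, 243, size=n).astype(float)

    fc = np.array([config.effect_table.get(m, 0.0) for m in names])
    log_acute = config.subject_sigma * rng_conc.standard_normal((n, p))
    for m, (age_slope, sex_offset) in config.confound_coeffs.items():
        j = names.index(m)
        log_acute[:, j] += age_slope * (ages - np.mean(ages)) + sex_offset * sexes
    acute = np.exp(log_acute)
    chronic = acute * 2.0 ** fc * np.exp(
        config.fc_noise_sd * rng_conc.standard_normal((n, p))
    )

    sample_ids, rows, phases = [], [], []
    for i, subj in enumerate(subjects):
        sample_ids += [f"{subj}_acute", f"{subj}_chronic"]
        rows += [acute[i], chronic[i]]
        phases += ["acute", "chronic"]
    conc = pd.DataFrame(rows, index=sample_ids, columns=names)
    dil = pd.Series(
        np.exp(config.dilution_sd * rng_conc.standard_normal(len(sample_ids))),
        index=sample_ids,
        name="dilution",
    )

    spectra: dict[str, Spectrum] = {}
    for sid in sample_ids:
        spectra[sid] = simulate_spectrum(
            concentrations=(conc.loc[sid] * dil[sid]).to_dict(),
            library=library,
            jitter_sd=config.jitter_sd,
            noise_sd=config.noise_sd,
            baseline_amplitude=config.baseline_amplitude,
            window=config.window,
            points=config.points,
            seed=rng_spec,
            tsp_height=config.tsp_height * dil[sid],
            tsp_offset=float(rng_spec.normal(0.0, config.jitter_sd)) if config.jitter_sd else 0.0,
            water_height=config.water_height * dil[sid],
            urea_height=config.urea_height * dil[sid],
        )

    pct = pd.DataFrame(
        {
            m: [
                percent_difference(acute[i, names.index(m)], chronic[i, names.index(m)])
                for i in range(n)
            ]
            for m in names
        },
        index=subjects,
    )

    clinical: list[ClinicalRecord] = []
    link_pct = pct[link.metabolite].to_numpy()
    for i, subj in enumerate(subjects):
        nihss = _clip_round(rng_clin.normal(5.5, 3.5), 0, 42)
        fim_ini = _clip_round(rng_clin.normal(98, 16), 18, 126)
        hand_ini = _clip_round(rng_clin.normal(4.0, 1.2), 1, 7)
        arm_ini = _clip_round(rng_clin.normal(4.0, 1.2), 1, 7)
        hand_signal = link.base + link.slope * link_pct[i]
        hand_imp = hand_signal + rng_clin.normal(0, link.noise_sd)
        arm_imp = hand_signal + rng_clin.normal(0, 3 * link.noise_sd)
        fim_imp = 18 + 8 * hand_signal + rng_clin.normal(0, 6)
        clinical.append(
            ClinicalRecord(
                subject_id=subj,
                stroke_type="ischemic" if rng_clin.random() < 0.7 else "hemorrhagic",
                sex="F" if sexes[i] else "M",
                age=ages[i],
                acute_day=acute_days[i],
                chronic_day=chronic_days[i],
                nihss_initial=nihss,
                fim_initial=fim_ini,
                fim_6mo=_clip_round(fim_ini + fim_imp, 18, 126),
                cmsa_hand_initial=hand_ini,
                cmsa_hand_6mo=_clip_round(hand_ini + hand_imp, 1, 7),
                cmsa_arm_initial=arm_ini,
                cmsa_arm_6mo=_clip_round(arm_ini + arm_imp, 1, 7),
            )
        )

    metadata = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, 2),
            "phase": phases,
            "age": np.repeat(ages, 2),
            "sex": np.repeat(sexes, 2),
            "collection_day": np.ravel(np.column_stack([acute_days, chronic_days])),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = CohortTruth(
        fold_changes={m: config.effect_table.get(m, 0.0) for m in names},
        informative={m: config.effect_table.get(m, 0.0) != 0.0 for m in names},
        confound_coeffs=dict(config.confound_coeffs),
        clinical_link=link,
        concentrations=conc,
        dilutions=dil,
        metabolite_pct_diff=pct,
    )
    return SimulatedCohort(spectra=spectra, metadata=metadata, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# lightweight paired feature cohorts (no spectral stage)

def simulate_paired_features(
    n_subjects: int,
    n_vars: int,
    planted: Mapping[int, float] | None = None,
    within_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Paired feature matrix with additive planted phase effects.

    Feature value = per-subject baseline N(0, 1) ± effect/2 by phase +
    N(0, within_sd) noise; ``planted`` maps variable index -> effect
    size (difference between phases).  Returns (X, y, groups) with
    y = +1 for chronic, -1 for acute and groups = subject indices, the
    inputs the selection and discriminant stages consume.  Used for
    calibration/power studies where the spectral stage is not under
    test.
    """
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_subjects, n_vars))
    effect = np.zeros(n_vars)
    for j, d in planted.items():
        effect[j] = d
    rows, y, groups, ids = [], [], [], []
    for s in range(n_subjects):
        for phase, sign in (("acute", -1.0), ("chronic", 1.0)):
            rows.append(base[s] + sign * effect / 2.0 + within_sd * rng.standard_normal(n_vars))
            y.append(sign)
            groups.append(s)
            ids.append(f"S{s + 1:02d}_{phase}")
    X = pd.DataFrame(rows, index=ids, columns=[f"v{j:03d}" for j in range(n_vars)])
    return X, np.array(y), np.array(groups)
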