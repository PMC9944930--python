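"""Synthetic ICU cohorts, annotator panels, and validation sets.

The study design this package analyses rests on two datasets that cannot be
redistributed: a 60-instance training panel independently labelled by 11 ICU
consultants, and terminal 5-hour patient trajectories ending in discharge or
death drawn from a credentialed-access critical-care database.  This module
emulates the *statistical structure* of both.

Each synthetic patient carries a latent severity ``z`` in [0, 1].  Six clinical
variables — adrenaline and noradrenaline infusion rates (µg/kg/min), FiO2,
SpO2, mean arterial pressure (MAP) and heart rate (HR) — are monotone noisy
transforms of ``z``: vasopressor doses and FiO2 rise with severity, MAP and
SpO2 fall.  Annotators band ``z`` into the five-point ordinal severity scale
A–E through personal thresholds, corrupted by three mechanisms mirroring the
judgment / bias / noise taxonomy of expert disagreement:

* ``bias`` — a systematic shift of all banding thresholds;
* ``noise_rate`` (ε) — random adjacent-category slips;
* ``inconsistency_rate`` (δ) — occasional use of a reduced-feature rule of
  thumb (banding on MAP alone) instead of the full assessment.

Terminal trajectories drift linearly from an admission severity toward the
terminal value with AR(1) noise; the outcome (died vs discharged alive) is
assigned from the final-hour severity via configurable cohort quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError

FEATURES = ["adrenaline", "noradrenaline", "fio2", "spo2", "map", "hr"]
LABELS = ["A", "B", "C", "D", "E"]

#: default banding thresholds on the latent [0, 1] severity axis
DEFAULT_THRESHOLDS = (0.2, 0.4, 0.6, 0.8)

#: thresholds of an annotator reluctant to use the extreme categories A and E
EXTREMITY_AVERSE_THRESHOLDS = (0.10, 0.38, 0.62, 0.92)


@dataclass(frozen=True)
class AnnotatorProfile:
    """Latent parameters of one synthetic annotator.

    Parameters
    ----------
    thresholds : four strictly increasing reals partitioning [0, 1] into the
        five severity bands A–E.
    bias : additive shift applied to every threshold (a positive bias makes
        the annotator grade patients as less severe).
    noise_rate : probability ε of an adjacent-category slip per record.
    inconsistency_rate : probability δ of judging via the reduced
        (MAP-only) rule instead of the full latent severity.
    """

    annotator_id: str
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS
    bias: float = 0.0
    noise_rate: float = 0.0
    inconsistency_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError(f"noise_rate must be in [0,1], got {self.noise_rate}")
        if not 0.0 <= self.inconsistency_rate <= 1.0:
            raise ConfigurationError(
                f"inconsistency_rate must be in [0,1], got {self.inconsistency_rate}"
            )
        shifted = self.shifted_thresholds
        if len(shifted) != 4 or np.any(np.diff(shifted) <= 0):
            raise ConfigurationError(
                f"thresholds must be 4 strictly increasing values after the bias "
                f"shift, got {shifted}"
            )

    @property
    def shifted_thresholds(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=float) + self.bias


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters.

    Outcome thresholds are cohort quantiles of final-hour severity: patients
    at or above ``outcome_high_quantile`` die, patients below
    ``outcome_low_quantile`` are discharged alive, and the middle band is
    indeterminate (excluded from validation sampling).
    """

    outcome_high_quantile: float = 0.75
    outcome_low_quantile: float = 0.25
    drift_sd: float = 0.10          # spread of admission severity around terminal
    ar_rho: float = 0.5             # AR(1) autocorrelation of hourly severity noise
    ar_sd: float = 0.03             # AR(1) innovation s.d.
    feature_noise: dict = field(
        default_factory=lambda: {
            "adrenaline": 0.03, "noradrenaline": 0.04, "fio2": 0.03,
            "spo2": 1.0, "map": 3.0, "hr": 5.0,
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.outcome_low_quantile <= self.outcome_high_quantile <= 1.0):
            raise ConfigurationError(
                "outcome quantiles must satisfy 0 <= low <= high <= 1, got "
                f"low={self.outcome_low_quantile}, high={self.outcome_high_quantile}"
            )
        if not 0.0 <= self.ar_rho < 1.0:
            raise ConfigurationError(f"ar_rho must be in [0,1), got {self.ar_rho}")
        for key in ("drift_sd", "ar_sd"):
            if getattr(self, key) < 0:
                raise ConfigurationError(f"{key} must be non-negative")
        missing = set(FEATURES) - set(self.feature_noise)
        if missing:
            raise ConfigurationError(f"feature_noise missing entries for {sorted(missing)}")
        if any(v < 0 for v in self.feature_noise.values()):
            raise ConfigurationError("feature noise s.d. values must be non-negative")


def features_from_severity(
    severity: np.ndarray, rng: np.random.Generator, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Derive the six clinical variables from latent severity plus noise.

    Vasopressor doses and FiO2 increase with severity; MAP and SpO2 decrease;
    HR increases.  All values are clipped to physiological ranges.
    """
    config = config or SimulationConfig()
    z = np.asarray(severity, dtype=float)
    sd = config.feature_noise
    n = z.shape[0]
    return pd.DataFrame(
        {
            "adrenaline": np.clip(0.6 * (z - 0.25) + rng.normal(0, sd["adrenaline"], n), 0.0, 2.0),
            "noradrenaline": np.clip(0.9 * z + rng.normal(0, sd["noradrenaline"], n), 0.0, 3.0),
            "fio2": np.clip(0.21 + 0.60 * z + rng.normal(0, sd["fio2"], n), 0.21, 1.0),
            "spo2": np.clip(99.0 - 18.0 * z + rng.normal(0, sd["spo2"], n), 50.0, 100.0),
            "map": np.clip(92.0 - 40.0 * z + rng.normal(0, sd["map"], n), 30.0, 140.0),
            "hr": np.clip(68.0 + 75.0 * z + rng.normal(0, sd["hr"], n), 20.0, 220.0),
        }
    )


def severity_band(severity, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Band latent severities into A–E labels at the given thresholds."""
    idx = np.searchsorted(np.asarray(thresholds, dtype=float), np.asarray(severity, float), side="right")
    return np.asarray(LABELS, dtype=object)[idx]


def reduced_feature_severity(records: pd.DataFrame) -> np.ndarray:
    """MAP-only severity proxy used as the annotators' rule-of-thumb shortcut.

    Inverts the mean MAP-vs-severity relationship of the generator, so it is
    correlated with — but systematically different from — the full assessment.
    """
    return np.clip((92.0 - records["map"].to_numpy(float)) / 40.0, 0.0, 1.0)


def generate_cohort(
    n_patients: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate terminal 5-hour trajectories with discharge/death outcomes.

    Returns a long-format table with one row per patient-hour (hours before
    outcome 5..1), columns ``patient_id, hours_before_outcome``, the six
    features, ``latent_severity`` and per-patient ``outcome`` in
    {discharged_alive, died, indeterminate}.
    """
    if n_patients < 2:
        raise ConfigurationError(f"n_patients must be >= 2, got {n_patients}")
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    z_term = rng.uniform(0.0, 1.0, n_patients)
    # admission severity pulled toward the cohort centre plus patient-level spread
    z_start = np.clip(0.5 + 0.6 * (z_term - 0.5) + rng.normal(0, config.drift_sd, n_patients), 0, 1)

    hours = np.array([5, 4, 3, 2, 1])
    frac = (hours - 1) / 4.0  # 1 at hour 5 (admission side), 0 at hour 1
    z = z_term[:, None] + frac[None, :] * (z_start - z_term)[:, None]

    # AR(1) hourly noise, hour 5 -> hour 1
    eps = np.zeros((n_patients, 5))
    eps[:, 0] = rng.normal(0, config.ar_sd, n_patients)
    for h in range(1, 5):
        eps[:, h] = config.ar_rho * eps[:, h - 1] + rng.normal(0, config.ar_sd, n_patients)
    z = np.clip(z + eps, 0.0, 1.0)

    z_final = z[:, -1]
    t_hi = np.quantile(z_final, config.outcome_high_quantile)
    t_lo = np.quantile(z_final, config.outcome_low_quantile)
    outcome = np.where(
        z_final >= t_hi, "died", np.where(z_final < t_lo, "discharged_alive", "indeterminate")
    )

    flat_z = z.ravel()
    table = features_from_severity(flat_z, rng, config)
    table.insert(0, "patient_id", np.repeat(np.arange(n_patients), 5))
    table.insert(1, "hours_before_outcome", np.tile(hours, n_patients))
    table["latent_severity"] = flat_z
    table["outcome"] = np.repeat(outcome, 5)
    return table


def simulate_annotator(profile: AnnotatorProfile, records: pd.DataFrame) -> np.ndarray:
    """Label records as one synthetic annotator would.

    Bands ``latent_severity`` under the profile's bias-shifted thresholds;
    with probability δ the band is instead computed from the MAP-only reduced
    rule; with probability ε the final label slips one category toward an
    adjacent class (at A or E the slip is forced inward).  Deterministic for
    a fixed ``profile.seed``.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    if "latent_severity" not in records.columns:
        raise ValueError("records must carry a latent_severity column for annotation")
    rng = np.random.default_rng(profile.seed)
    n = len(records)
    thr = profile.shifted_thresholds

    full = np.searchsorted(thr, records["latent_severity"].to_numpy(float), side="right")
    alt = np.searchsorted(thr, reduced_feature_severity(records), side="right")
    band = np.where(rng.random(n) < profile.inconsistency_rate, alt, full)

    slip = rng.random(n) < profile.noise_rate
    direction = rng.integers(0, 2, n) * 2 - 1
    slipped = band + direction
    slipped = np.where(slipped < 0, 1, slipped)   # below A reflects to B
    slipped = np.where(slipped > 4, 3, slipped)   # above E reflects to D
    band = np.where(slip, slipped, band)
    return np.asarray(LABELS, dtype=object)[band]


def default_profiles(seed: int = 0) -> list[AnnotatorProfile]:
    """The default 11-annotator panel: 4 consistent and 7 noisy profiles.

    The noisy group combines adjacent-category slips (ε ≥ 0.3), reduced-rule
    inconsistency, threshold bias, and extremity-averse thresholds, giving
    the mixed-learnability regime in which a learnability-filtered consensus
    is expected to beat a plain majority vote.
    """
    base = int(seed) % 2**31

    def s(i: int) -> int:
        return (base * 10007 + i) % 2**31

    consistent = [
        AnnotatorProfile("C1", DEFAULT_THRESHOLDS, 0.00, 0.00, 0.00, s(1)),
        AnnotatorProfile("C2", DEFAULT_THRESHOLDS, 0.01, 0.01, 0.00, s(2)),
        AnnotatorProfile("C3", DEFAULT_THRESHOLDS, -0.01, 0.02, 0.00, s(3)),
        AnnotatorProfile("C4", DEFAULT_THRESHOLDS, 0.00, 0.03, 0.02, s(4)),
    ]
    ea = EXTREMITY_AVERSE_THRESHOLDS
    noisy = [
        AnnotatorProfile("C5", ea, 0.05, 0.30, 0.30, s(5)),
        AnnotatorProfile("C6", ea, -0.06, 0.35, 0.30, s(6)),
        AnnotatorProfile("C7", ea, 0.07, 0.40, 0.20, s(7)),
        AnnotatorProfile("C8", ea, 0.02, 0.30, 0.40, s(8)),
        AnnotatorProfile("C9", ea, -0.04, 0.45, 0.30, s(9)),
        AnnotatorProfile("C10", ea, 0.06, 0.35, 0.35, s(10)),
        AnnotatorProfile("C11", ea, 0.00, 0.50, 0.20, s(11)),
    ]
    return consistent + noisy


@dataclass
class AnnotatedPanel:
    """A complete multi-annotator training panel.

    ``features`` holds the six clinical variables indexed by instance id;
    ``labels`` holds one A–E column per annotator over the same index.  The
    latent severity used to produce the labels is kept privately for
    simulation-side checks and is never serialised.
    """

    features: pd.DataFrame
    labels: pd.DataFrame
    latent_severity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ConfigurationError("features and labels must share an index")
        if self.labels.isna().any().any():
            raise ConfigurationError("panel is incomplete: missing labels")
        bad = set(np.unique(self.labels.to_numpy())) - set(LABELS)
        if bad:
            raise ConfigurationError(f"labels outside the A-E alphabet: {sorted(bad)}")

    @property
    def annotator_ids(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def n_records(self) -> int:
        return len(self.features)

    def to_csv(self, path) -> None:
        """Write instance_id, the six features, then one label column per annotator."""
        out = self.features.copy()
        for col in self.labels.columns:
            out[f"label_{col}"] = self.labels[col]
        out.to_csv(path, index_label="instance_id")

    @classmethod
    def from_csv(cls, path) -> "AnnotatedPanel":
        table = pd.read_csv(path, index_col="instance_id")
        label_cols = [c for c in table.columns if c.startswith("label_")]
        labels = table[label_cols].rename(columns=lambda c: c[len("label_"):])
        return cls(features=table[FEATURES].copy(), labels=labels)


def generate_annotated_panel(
    n_records: int = 60,
    profiles: list[AnnotatorProfile] | None = None,
    seed: int = 42,
) -> AnnotatedPanel:
    """Generate a complete annotated panel (default: 60 records, 11 annotators)."""
    if n_records < 10:
        raise ConfigurationError(f"n_records must be >= 10, got {n_records}")
    profiles = profiles if profiles is not None else default_profiles(seed)
    if len(profiles) < 2:
        raise ConfigurationError("need at least 2 annotator profiles")
    ids = [p.annotator_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate annotator ids in profiles: {ids}")

    rng = np.random.default_rng(seed)
    z = rng.uniform(0.0, 1.0, n_records)
    features = features_from_severity(z, rng)
    hidden = features.copy()
    hidden["latent_severity"] = z
    labels = pd.DataFrame(
        {p.annotator_id: simulate_annotator(p, hidden) for p in profiles},
        index=features.index,
    )
    return AnnotatedPanel(features=features, labels=labels, latent_severity=z)


@dataclass
class ValidationSet:
    """Terminal patient records with ground-truth discharge status.

    ``layout='static'`` keeps the single record one hour before outcome;
    ``layout='temporal'`` keeps the five records at hours 5..1.
    """

    records: pd.DataFrame
    layout: str

    def __post_init__(self) -> None:
        if self.layout not in ("static", "temporal"):
            raise ConfigurationError(f"unknown layout {self.layout!r}")
        per = self.records.groupby("patient_id").size()
        want = 1 if self.layout == "static" else 5
        if not (per == want).all():
            raise ConfigurationError(
                f"{self.layout} layout requires exactly {want} record(s) per patient"
            )

    @property
    def outcomes(self) -> pd.Series:
        """Per-patient outcome, indexed by patient_id."""
        return self.records.groupby("patient_id")["outcome"].first()

    @property
    def n_alive(self) -> int:
        return int((self.outcomes == "discharged_alive").sum())

    @property
    def n_died(self) -> int:
        return int((self.outcomes == "died").sum())

    def feature_table(self) -> pd.DataFrame:
        return self.records[FEATURES]

    def to_csv(self, path) -> None:
        cols = ["patient_id", "hours_before_outcome", *FEATURES, "outcome"]
        self.records[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layout: str) -> "ValidationSet":
        return cls(records=pd.read_csv(path), layout=layout)


def make_validation_sets(
    cohort: pd.DataFrame,
    n_alive: int,
    n_died: int,
    layout: str = "static",
    seed: int = 0,
) -> ValidationSet:
    """Sample a class-balanced validation set from a generated cohort.

    Sampling is without replacement over patients; indeterminate-outcome
    patients are never sampled.
    """
    rng = np.random.default_rng(seed)
    per_patient = cohort.groupby("patient_id")["outcome"].first()
    chosen = []
    for outcome, n_want in (("discharged_alive", n_alive), ("died", n_died)):
        pool = per_patient.index[per_patient == outcome].to_numpy()
        if len(pool) < n_want:
            raise SamplingError(
                f"cohort has only {len(pool)} '{outcome}' patients, {n_want} requested"
            )
        chosen.append(rng.choice(pool, size=n_want, replace=False))
    keep = np.concatenate(chosen)
    sub = cohort[cohort["patient_id"].isin(keep)].copy()
    if layout == "static":
        sub = sub[sub["hours_before_outcome"] == 1]
    elif layout != "temporal":
        raise ConfigurationError(f"unknown layout {layout!r}")
    sub = sub.drop(columns=["latent_severity"]).sort_values(
        ["patient_id", "hours_before_outcome"], ascending=[True, False]
    )
    return ValidationSet(records=sub.reset_index(drop=True), layout=layout)


def graded_noise_profiles(
    noise_rates, thresholds=DEFAULT_THRESHOLDS, seed: int = 0
) -> list[AnnotatorProfile]:
    """Profiles differing only in the slip rate ε — used for calibration checks."""
    base = int(seed) % 2**31
    return [
        AnnotatorProfile(f"E{i}", thresholds, 0.0, float(eps), 0.0, (base * 7919 + i) % 2**31)
        for i, eps in enumerate(noise_rates)
    ]
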