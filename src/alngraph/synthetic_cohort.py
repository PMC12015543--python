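"""Synthetic breast-cancer cohort generation.

Generates per-patient tables whose marginal distributions and
feature-outcome effect structure emulate a published breast-cancer
cohort assessed for axillary lymph node metastasis (ALNM): age and
ultrasound tumour size as truncated normals, ordinal tumour
location / histologic type / BI-RADS codes, immunohistochemical
markers (ER, PR, Ki-67 as percentages; HER2 binary), and nine binary
axillary-ultrasound findings ("Terms").

The generative mechanism is a latent logistic link: the binary ALN
label is drawn first at the configured prevalence, and every feature
is then drawn conditionally on the label such that the *population*
log odds-ratio between feature and label equals the configured
per-feature effect exactly, while the feature's marginal distribution
equals its configured target exactly.  This closed-loop construction
makes planted effects directly recoverable by univariate logistic
screening, which is what the downstream pipeline tests exploit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

ID_COLUMN = "patient_id"
LABEL_COLUMN = "aln_status"

TERM_FEATURES = tuple(f"term{i}" for i in range(1, 10))
CONTINUOUS_FEATURES = ("age", "us_size", "er", "pr", "ki67")
ORDINAL_FEATURES = ("location", "tumor_type", "birads")
BINARY_FEATURES = ("her2",) + TERM_FEATURES

FEATURE_COLUMNS = (
    "age", "us_size", "location", "tumor_type", "birads",
    "er", "pr", "ki67", "her2",
) + TERM_FEATURES

COHORT_COLUMNS = (ID_COLUMN,) + FEATURE_COLUMNS + (LABEL_COLUMN,)

#: inclusive code ranges for the ordinal features
ORDINAL_RANGES = {"location": (1, 4), "tumor_type": (1, 3), "birads": (1, 4)}

# Marginal positivity of the nine axillary-US findings in the training
# cohort the generator emulates.  Term 8 had zero positives there (a
# degenerate marginal); its default is the non-degenerate test-cohort
# rate so that the default generator exercises all nine findings.
DEFAULT_TERM_BASE_RATES = {
    "term1": 0.380, "term2": 0.067, "term3": 0.165, "term4": 0.273,
    "term5": 0.195, "term6": 0.075, "term7": 0.028, "term8": 0.017,
    "term9": 0.174,
}

# Per-feature univariate log odds of ALNM, on the raw feature scale
# (per year, per mm, per ordinal step, per percent, per positive flag).
DEFAULT_EFFECT_LOG_ODDS = {
    "age": 0.0010, "location": 0.1788, "us_size": 0.0575,
    "tumor_type": 0.0152, "birads": -0.1867, "er": 0.0003,
    "pr": -0.0024, "ki67": 0.0033, "her2": 0.1766,
    "term1": 0.9057, "term2": 2.6872, "term3": 1.1147, "term4": 0.6735,
    "term5": 2.4585, "term6": 2.0237, "term7": 2.0663, "term8": 0.0,
    "term9": 1.4958,
}

# Ordinal category marginals (training-cohort proportions, normalised).
DEFAULT_ORDINAL_PROBS = {
    "location": (0.270, 0.139, 0.172, 0.418),     # UI, LI, LL, UL quadrant
    "tumor_type": (0.884, 0.026, 0.090),          # IDC, ILC, other
    "birads": (0.051, 0.275, 0.451, 0.223),       # 4A, 4B, 4C, 5
}

# Immunohistochemical percentages: (mean, sd) on the 0-100 scale.
# The emulated cohort reports these only as positive/negative rates, so
# the continuous shapes are a modelling choice (see docs/methods.md).
DEFAULT_MARKER_PARAMS = {"er": (60.0, 30.0), "pr": (55.0, 30.0), "ki67": (40.0, 25.0)}

DEFAULT_HER2_RATE = 0.223

AGE_BOUNDS = (18.0, 100.0)
SIZE_BOUNDS = (0.0, 40.0)
MARKER_BOUNDS = (0.0, 100.0)


class CohortParameterError(ValueError):
    """Raised for invalid cohort-generation parameters."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the emulated training cohort: 42.3% ALNM
    prevalence, age 50.46 +/- 10.36 years, ultrasound size
    19.06 +/- 6.57 mm, and the per-term base rates and per-feature
    log-odds effects listed above.
    """

    n_patients: int = 584
    prevalence: float = 0.423
    age_mean: float = 50.46
    age_sd: float = 10.36
    size_mean: float = 19.06
    size_sd: float = 6.57
    term_base_rates: dict = field(default_factory=lambda: dict(DEFAULT_TERM_BASE_RATES))
    effect_log_odds: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_LOG_ODDS))
    ordinal_probs: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ORDINAL_PROBS.items()})
    marker_params: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PARAMS))
    her2_rate: float = DEFAULT_HER2_RATE
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise CohortParameterError(f"n_patients must be a non-negative integer, got {self.n_patients!r}")
        for name, p in [("prevalence", self.prevalence), ("her2_rate", self.her2_rate),
                        *self.term_base_rates.items()]:
            if not 0.0 <= p <= 1.0:
                raise CohortParameterError(f"probability {name}={p} outside [0, 1]")
        for name, sd in [("age_sd", self.age_sd), ("size_sd", self.size_sd),
                         *((k, v[1]) for k, v in self.marker_params.items())]:
            if not sd > 0:
                raise CohortParameterError(f"standard deviation {name}={sd} must be > 0")
        for feat, probs in self.ordinal_probs.items():
            probs = np.asarray(probs, dtype=float)
            # printed cohort percentages round to ~3 decimals; normalised at draw time
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=5e-3):
                raise CohortParameterError(f"ordinal probabilities for {feat} must be non-negative and sum to 1")
        unknown = set(self.effect_log_odds) - set(FEATURE_COLUMNS)
        if unknown:
            raise CohortParameterError(f"effect_log_odds for unknown features: {sorted(unknown)}")

    # flat config-file round trip -------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CohortParameterError(f"unknown CohortSpec keys: {sorted(unknown)}")
        spec = cls(**raw)
        spec.ordinal_probs = {k: tuple(v) for k, v in spec.ordinal_probs.items()}
        spec.marker_params = {k: tuple(v) for k, v in spec.marker_params.items()}
        return spec


def _tilted_conditionals(base_probs: np.ndarray, codes: np.ndarray,
                         effect: float, prevalence: float):
    """Class-conditional categorical distributions with an exact planted effect.

    Returns (Q0, Q1) over `codes` such that the mixture
    (1-p)*Q0 + p*Q1 equals `base_probs` exactly and
    log[Q1(c)/Q0(c)] - log[Q1(c')/Q0(c')] = effect*(c - c'), i.e. a
    univariate logistic regression of the label on the code has
    population slope exactly `effect`.
    """
    base = np.asarray(base_probs, dtype=float)
    codes = np.asarray(codes, dtype=float)
    p = float(prevalence)
    if effect == 0.0 or p == 0.0 or p == 1.0 or (base > 0).sum() <= 1:
        return base.copy(), base.copy()
    r = np.exp(effect * (codes - codes.mean()))  # centred to keep k near 1

    def total_q0(log_k):
        k = np.exp(log_k)
        return np.sum(base / ((1.0 - p) + p * k * r)) - 1.0

    # total_q0 is strictly decreasing in k; bracket widely in log space
    lo, hi = -80.0, 80.0
    log_k = brentq(total_q0, lo, hi, xtol=1e-14)
    k = np.exp(log_k)
    q0 = base / ((1.0 - p) + p * k * r)
    q1 = k * r * q0
    return q0, q1


def _binary_conditionals(base_rate: float, effect: float, prevalence: float):
    """(P(x=1|y=0), P(x=1|y=1)) with marginal = base_rate and log-OR = effect."""
    q0, q1 = _tilted_conditionals(
        np.array([1.0 - base_rate, base_rate]), np.array([0.0, 1.0]),
        effect, prevalence)
    return q0[1], q1[1]


def _truncated_normal(rng, mean0, shift, sd, bounds, y):
    """Per-row truncated normal with class-dependent location mean0 + shift*y."""
    loc = mean0 + shift * y
    a = (bounds[0] - loc) / sd
    b = (bounds[1] - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table from `spec`.

    Labels are Bernoulli(prevalence).  Continuous features use
    class-shifted truncated normals with shift = effect * sd**2 (the
    shift that induces the configured logistic slope under a
    common-variance normal model); ordinal and binary features use the
    exact tilted-conditional construction so planted log odds-ratios
    are exact.  Same seed => bit-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_patients)
    eff = {**DEFAULT_EFFECT_LOG_ODDS, **spec.effect_log_odds}

    y = rng.binomial(1, spec.prevalence, size=n)
    width = max(4, len(str(max(n, 1))))
    data = {ID_COLUMN: [f"P{i + 1:0{width}d}" for i in range(n)]}

    # continuous: age, size, IHC markers
    cont_params = {
        "age": (spec.age_mean, spec.age_sd, AGE_BOUNDS),
        "us_size": (spec.size_mean, spec.size_sd, SIZE_BOUNDS),
        "er": (*spec.marker_params["er"], MARKER_BOUNDS),
        "pr": (*spec.marker_params["pr"], MARKER_BOUNDS),
        "ki67": (*spec.marker_params["ki67"], MARKER_BOUNDS),
    }
    for feat in CONTINUOUS_FEATURES:
        mean, sd, bounds = cont_params[feat]
        shift = eff[feat] * sd ** 2
        mean0 = mean - spec.prevalence * shift
        if n:
            data[feat] = _truncated_normal(rng, mean0, shift, sd, bounds, y)
        else:
            data[feat] = np.empty(0, dtype=float)

    for feat in ORDINAL_FEATURES:
        probs = np.asarray(spec.ordinal_probs[feat], dtype=float)
        probs = probs / probs.sum()
        lo, hi = ORDINAL_RANGES[feat]
        codes = np.arange(lo, hi + 1)
        if len(probs) != len(codes):
            raise CohortParameterError(
                f"{feat}: expected {len(codes)} category probabilities, got {len(probs)}")
        q0, q1 = _tilted_conditionals(probs, codes, eff[feat], spec.prevalence)
        u = rng.random(n)
        cdf0, cdf1 = np.cumsum(q0), np.cumsum(q1)
        idx = np.where(y == 1,
                       np.searchsorted(cdf1, u, side="right"),
                       np.searchsorted(cdf0, u, side="right"))
        data[feat] = codes[np.minimum(idx, len(codes) - 1)]

    bin_rates = {"her2": spec.her2_rate, **{t: spec.term_base_rates[t] for t in TERM_FEATURES}}
    for feat in BINARY_FEATURES:
        q0, q1 = _binary_conditionals(bin_rates[feat], eff[feat], spec.prevalence)
        prob = np.where(y == 1, q1, q0)
        data[feat] = rng.binomial(1, prob, size=n) if n else np.empty(0, dtype=int)

    data[LABEL_COLUMN] = y
    table = pd.DataFrame(data, columns=list(COHORT_COLUMNS))
    for col in ORDINAL_FEATURES + BINARY_FEATURES + (LABEL_COLUMN,):
        table[col] = table[col].astype(np.int64)
    return table


def split_cohort(table: pd.DataFrame, ratio: float = 0.8,
                 stratified: bool = True, seed: int = 0):
    """Random train/test partition of a cohort.

    With `stratified`, each label class contributes floor(n_class*ratio)
    patients to the training part, which keeps the two class proportions
    within one patient's worth of each other.  Row order of the input is
    preserved within each part.  Returns (train, test).
    """
    if not 0.0 < ratio < 1.0:
        raise CohortParameterError(f"split ratio must lie in (0, 1), got {ratio}")
    if len(table) == 0:
        raise CohortParameterError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    positions = np.arange(len(table))
    if stratified:
        train_pos = []
        for cls in (0, 1):
            cls_pos = positions[table[LABEL_COLUMN].to_numpy() == cls]
            perm = rng.permutation(cls_pos)
            train_pos.append(perm[: int(np.floor(len(cls_pos) * ratio))])
        train_idx = np.sort(np.concatenate(train_pos)) if train_pos else np.array([], int)
    else:
        perm = rng.permutation(positions)
        train_idx = np.sort(perm[: int(np.floor(len(table) * ratio))])
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    return table.iloc[mask].reset_index(drop=True), table.iloc[~mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV interface

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    issues = validate_cohort(table)
    if issues:
        raise CohortSchemaError(path, issues)
    for col in ORDINAL_FEATURES + BINARY_FEATURES + (LABEL_COLUMN,):
        table[col] = table[col].astype(np.int64)
    return table


class CohortSchemaError(ValueError):
    def __init__(self, path, issues):
        self.issues = issues
        super().__init__(f"{path}: invalid cohort table: " + "; ".join(issues))


def validate_cohort(table: pd.DataFrame) -> list:
    """Schema check for a cohort table; returns a list of issue strings."""
    issues = []
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        issues.append(f"missing columns: {missing}")
        return issues
    extra = [c for c in table.columns if c not in COHORT_COLUMNS]
    if extra:
        issues.append(f"unexpected columns: {extra}")
    if table[ID_COLUMN].duplicated().any():
        dups = table.loc[table[ID_COLUMN].duplicated(), ID_COLUMN].tolist()
        issues.append(f"duplicate patient_id values: {dups}")
    for col in FEATURE_COLUMNS + (LABEL_COLUMN,):
        vals = table[col]
        if vals.isna().any():
            issues.append(f"column {col}: missing values at rows "
                          f"{list(np.flatnonzero(vals.isna().to_numpy()))}")
            continue
        if col in BINARY_FEATURES + (LABEL_COLUMN,):
            bad = ~vals.isin([0, 1])
            if bad.any():
                issues.append(f"column {col}: non-binary values at rows "
                              f"{list(np.flatnonzero(bad.to_numpy()))}")
        elif col in ORDINAL_FEATURES:
            lo, hi = ORDINAL_RANGES[col]
            bad = (vals < lo) | (vals > hi) | (vals != vals.astype(int))
            if bad.any():
                issues.append(f"column {col}: codes outside [{lo}, {hi}] at rows "
                              f"{list(np.flatnonzero(bad.to_numpy()))}")
    return issues
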