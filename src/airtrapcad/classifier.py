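"""Two-class Gaussian Bayes classifier and linear severity models.

The two classes are normal (omega_1) and patient (omega_2); a single
air-trapping feature x (area or volume variation) is modelled per class as
a univariate Gaussian N(mu, sigma^2) with a prior p(omega).  The minimum-
error decision is the likelihood-ratio rule

    l_r(x) = p(x|omega_1) / p(x|omega_2) > p(omega_2)/p(omega_1)
        =>  x in omega_1,

which is identical to comparing posteriors.  The decision boundary solves
the quadratic obtained from equating log-posteriors: unequal class
variances give up to two real roots; equal variances a single one.  Ties
at the boundary go to the patient class (a screening context favours
sensitivity).

Severity is read off the same models: the patient's volume variation, its
z-score against the normal class, its posterior patient probability, and
its residual from each class's least-squares dV-dS line.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger("airtrapcad.classifier")

from .errors import FitError, ParameterError
from .features import FeatureRecord

NORMAL = "normal"
PATIENT = "patient"

#: Posterior-equality tolerance required of every returned threshold.
THRESHOLD_TOL = 1e-9


@dataclass
class GaussianClassModel:
    """Per-class univariate Gaussian with prior probability."""

    class_label: str
    mu: float
    sigma: float
    prior: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.prior < 1):
            raise ParameterError(f"prior must lie in (0, 1), got {self.prior}")

    def logpdf(self, x) -> np.ndarray:
        return stats.norm.logpdf(x, self.mu, self.sigma)

    def pdf(self, x) -> np.ndarray:
        return stats.norm.pdf(x, self.mu, self.sigma)


@dataclass
class BayesRule:
    """Fitted decision rule for one feature.

    ``models`` is (normal, patient); ``thresholds`` holds the posterior
    crossing points, the classification-relevant root (between the class
    means) first when it exists, any remaining roots after it in ascending
    order.
    """

    feature_name: str
    models: Tuple[GaussianClassModel, GaussianClassModel]
    thresholds: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_name not in ("delta_S_N", "delta_V_N"):
            raise ParameterError(f"unknown feature {self.feature_name!r}")
        labels = tuple(m.class_label for m in self.models)
        if labels != (NORMAL, PATIENT):
            raise ParameterError(f"models must be (normal, patient), got {labels}")
        total = sum(m.prior for m in self.models)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class priors must sum to 1, got {total}")

    @classmethod
    def fit(
        cls,
        records: Iterable[FeatureRecord],
        feature_name: str = "delta_V_N",
        prior_mode: str = "empirical",
    ) -> "BayesRule":
        records = list(records)
        values = [getattr(r, feature_name) for r in records]
        labels = [r.label for r in records]
        models = fit_class_models(values, labels, prior_mode)
        rule = cls(feature_name, models)
        rule.thresholds = decision_thresholds(models)
        return rule


def fit_class_models(
    values: Sequence[float],
    labels: Sequence[str],
    prior_mode: str = "empirical",
) -> Tuple[GaussianClassModel, GaussianClassModel]:
    """Fit the (normal, patient) Gaussians from labelled feature values.

    Means are sample means, sigmas sample standard deviations (n-1
    denominator); priors are class frequencies (``"empirical"``) or 0.5
    each (``"equal"``).
    """
    if prior_mode not in ("empirical", "equal"):
        raise ParameterError(f"prior_mode must be empirical/equal, got {prior_mode!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ParameterError("values and labels differ in length")
    models = []
    n_total = len(values)
    for lbl in (NORMAL, PATIENT):
        x = values[labels == lbl]
        if len(x) < 2:
            raise FitError(f"class {lbl!r} has {len(x)} samples; need >= 2")
        sigma = float(np.std(x, ddof=1))
        if sigma <= 0:
            raise FitError(f"class {lbl!r} has zero variance")
        prior = len(x) / n_total if prior_mode == "empirical" else 0.5
        models.append(GaussianClassModel(lbl, float(np.mean(x)), sigma, prior))
    return tuple(models)


def likelihood_ratio(x, rule: BayesRule) -> np.ndarray:
    """l_r(x) = p(x|normal) / p(x|patient)."""
    m1, m2 = rule.models
    with np.errstate(over="ignore"):  # a ratio of densities may be inf
        return np.exp(m1.logpdf(x) - m2.logpdf(x))


def decision_thresholds(
    models: Tuple[GaussianClassModel, GaussianClassModel],
) -> List[float]:
    """Solve the posterior-equality quadratic for the decision boundary.

    log[p1 N(x; mu1, s1)] = log[p2 N(x; mu2, s2)] is quadratic in x when
    the variances differ (up to two real roots) and linear when they are
    equal (one root).  Returns the classification-relevant root — the one
    between the class means — first when it exists, the remaining real
    roots after it in ascending order.  No real root (one posterior
    dominating everywhere) gives an empty list; classification then falls
    back to direct posterior comparison.
    """
    m1, m2 = models
    s1sq, s2sq = m1.sigma**2, m2.sigma**2
    a = 0.5 / s2sq - 0.5 / s1sq
    b = m1.mu / s1sq - m2.mu / s2sq
    c = (
        m2.mu**2 / (2 * s2sq)
        - m1.mu**2 / (2 * s1sq)
        + math.log((m1.prior * m2.sigma) / (m2.prior * m1.sigma))
    )
    if abs(a) < 1e-300:  # equal variances -> linear
        if b == 0:
            return []
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            return []
        # numerically stable form, then Newton polish against cancellation
        q = -0.5 * (b + math.copysign(math.sqrt(disc), b if b != 0 else 1.0))
        roots = sorted({q / a, c / q} if q != 0 else {0.0})
        for _ in range(3):
            roots = [
                r - (a * r * r + b * r + c) / (2 * a * r + b)
                if 2 * a * r + b != 0
                else r
                for r in roots
            ]
        roots = sorted(roots)
    lo, hi = sorted((m1.mu, m2.mu))
    between = [r for r in roots if lo <= r <= hi]
    rest = sorted(r for r in roots if r not in between)
    ordered = between[:1] + sorted([r for r in between[1:]] + rest)
    for r in ordered:
        gap = abs(float(_posterior_patient(r, models)) - 0.5)
        # fp conditioning: the posterior gap is only computable to about
        # eps times the magnitude of the log-densities being cancelled,
        # which exceeds the nominal tolerance for extreme models (tiny
        # sigmas, far roots)
        cond = (abs(float(m1.logpdf(r))) + abs(float(m2.logpdf(r))) + abs(c)) * 1e-15
        if gap > max(THRESHOLD_TOL, cond):
            raise FitError(f"threshold {r} violates posterior equality (gap {gap:.2e})")
        if gap > THRESHOLD_TOL:
            logger.warning(
                "threshold %.6g: posterior gap %.2e limited by fp conditioning", r, gap
            )
    return ordered


def _posterior_patient(x, models) -> np.ndarray:
    m1, m2 = models
    log1 = np.log(m1.prior) + m1.logpdf(x)
    log2 = np.log(m2.prior) + m2.logpdf(x)
    # stable softmax over two terms
    m = np.maximum(log1, log2)
    e1, e2 = np.exp(log1 - m), np.exp(log2 - m)
    return e2 / (e1 + e2)


def posterior_patient(x, rule: BayesRule) -> np.ndarray:
    """p(patient | x) under the fitted rule."""
    return _posterior_patient(x, rule.models)


def classify(record, rule: BayesRule):
    """Label a record (or bare feature value) and return p(patient|x).

    Equivalent to the likelihood-ratio rule; a tie at the boundary is
    broken toward the patient class.
    """
    x = getattr(record, rule.feature_name) if hasattr(record, rule.feature_name) else float(record)
    post = float(_posterior_patient(x, rule.models))
    label = NORMAL if post < 0.5 else PATIENT
    return label, post


@dataclass
class LinearFit:
    """Least-squares line dV_N = slope * dS_N + intercept for one class."""

    class_label: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_squared) or self.r_squared > 1 + 1e-12:
            raise ParameterError(f"invalid r_squared {self.r_squared}")

    def predict(self, delta_S_N: float) -> float:
        return self.slope * delta_S_N + self.intercept


def fit_severity_lines(records: Iterable[FeatureRecord]) -> Dict[str, LinearFit]:
    """Per-class ordinary least squares of dV_N on dS_N.

    The fitted lines model how volume and area variation co-vary within
    each class; a patient's deviation from them is part of the severity
    report.
    """
    records = list(records)
    fits: Dict[str, LinearFit] = {}
    for lbl in (NORMAL, PATIENT):
        pts = [(r.delta_S_N, r.delta_V_N) for r in records if r.label == lbl]
        if len(pts) < 3:
            raise FitError(f"class {lbl!r} has {len(pts)} records; need >= 3 for OLS")
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) == 0:
            raise FitError(f"class {lbl!r}: zero variance in delta_S_N")
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        fits[lbl] = LinearFit(lbl, float(slope), float(intercept), r2)
    return fits


def severity_score(
    record: FeatureRecord,
    rule: BayesRule,
    fits: Dict[str, LinearFit],
) -> Dict[str, float]:
    """Severity report for one subject.

    Contains the volume variation itself, its air-trapping z-score
    ``(mu_normal - dV_N) / sigma_normal`` (0 = typical healthy emptying,
    larger = more trapping), the posterior patient probability, and the
    residual of dV_N from each class's severity line.
    """
    normal_model = rule.models[0]
    dv = record.delta_V_N
    z = (normal_model.mu - dv) / normal_model.sigma
    _, post = classify(record, rule)
    report = {
        "delta_V_N": dv,
        "air_trapping_z": z,
        "posterior_patient": post,
    }
    for lbl, fit in fits.items():
        report[f"residual_{lbl}_line"] = dv - fit.predict(record.delta_S_N)
    return report


# --------------------------------------------------------------------------
# Model persistence (JSON)

def save_models(
    path,
    rules: Dict[str, BayesRule],
    fits: Optional[Dict[str, LinearFit]] = None,
) -> None:
    """Serialize fitted rules (per feature) and severity lines to JSON."""
    payload = {
        "rules": {
            name: {
                "feature_name": r.feature_name,
                "models": [asdict(m) for m in r.models],
                "thresholds": list(r.thresholds),
            }
            for name, r in rules.items()
        },
        "severity_lines": {lbl: asdict(f) for lbl, f in (fits or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_models(path):
    with open(path) as fh:
        payload = json.load(fh)
    rules = {}
    for name, r in payload["rules"].items():
        models = tuple(GaussianClassModel(**m) for m in r["models"])
        rule = BayesRule(r["feature_name"], models)
        rule.thresholds = list(r["thresholds"])
        rules[name] = rule
    fits = {lbl: LinearFit(**f) for lbl, f in payload.get("severity_lines", {}).items()}
    return rules, fits
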