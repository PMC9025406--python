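"""Perturbation-based feature contributions and the relative-contribution test.

For a fitted sequence model, the contribution of feature *j* to one
patient's prediction is measured by removal perturbation: each occurrence
of the feature in the input sequence is deleted one at a time (others left
intact) and the drops in the predicted probability are summed,

    FC_j(patient) = sum_occurrences [ score(original) - score(one removed) ].

The relative contribution of the feature is the ratio of mean FC among
event (case) patients to mean FC among non-event (control) patients,

    RC = ( sum FC_event / m ) / ( sum FC_no-event / n ),

with a delta-method variance on the log scale built from the within-group
coefficients of variation,

    Var(ln RC) = (sd_event / mean_event)^2 / m
               + (sd_no-event / mean_no-event)^2 / n,

a log-symmetric 95% interval  exp(ln RC +- 1.96 sqrt(Var)),  and a
two-sided p-value from  z = ln RC / sqrt(Var)  under a standard-normal
reference. p-values are Bonferroni-adjusted over the number of features
actually tested, and Benjamini-Hochberg q-values are reported alongside.
A feature is flagged significant when the Bonferroni-adjusted p is below
0.05 *and* the interval excludes 1; RC > 1 marks a risk feature, RC < 1 a
protective one.

Group-membership convention: by default every patient contributes an FC row
to each feature — zero when the feature is absent from the history, since a
feature that never occurs contributes nothing — and m/n count all patients
with and without the event. This makes RC sensitive to carrier *prevalence*
as well as to per-carrier burden; with near-additive models RC approximately
equals the ratio of mean occurrence counts between the groups, which is
exactly the quantity a risk-factor screen wants. The alternative
``group_mode="carriers"`` restricts rows (and m/n) to carriers only; it
conditions away the prevalence difference and is retained for sensitivity
analyses. Support for a feature is judged by its carrier counts in both
groups regardless of mode. ``sd`` is the sample standard deviation
(denominator m-1 / n-1).

Scale convention: deltas are measured on the *logit* scale by default
(``fc_scale="probability"`` is available). On the probability scale the
sigmoid's saturation couples a feature's delta to the patient's overall
risk — high-risk patients sit on a flat part of the curve, so removal
deltas of genuine risk features come out *smaller* among events and the RC
direction inverts. On the logit scale the per-occurrence delta is
approximately the feature's additive effect, so FC is roughly
(effect) x (occurrence count), the effect cancels in the ratio, and RC
compares occurrence burden between event and no-event carriers — positive
effects yield RC > 1, protective ones RC < 1. Protective features carry
negative FC in both groups; the ratio is therefore taken over group means
of *matching sign* (a mean of zero or means of opposite sign exclude the
feature as "sign-invalid").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .encoding import EncodedSample
from .models import SequenceClassifier

logger = logging.getLogger(__name__)


@dataclass
class ContributionConfig:
    min_support: int = 10            # carriers required in each group
    group_mode: str = "all"          # "all" | "carriers"
    sample_mode: str = "closest"     # case sample used per patient: "closest" | "mean"
    fc_scale: str = "logit"          # "logit" | "probability"
    alpha: float = 0.05

    def validate(self) -> None:
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2 (sample sd needs two points)")
        if self.group_mode not in ("carriers", "all"):
            raise ValueError("group_mode must be 'carriers' or 'all'")
        if self.sample_mode not in ("closest", "mean"):
            raise ValueError("sample_mode must be 'closest' or 'mean'")
        if self.fc_scale not in ("logit", "probability"):
            raise ValueError("fc_scale must be 'logit' or 'probability'")


# ---------------------------------------------------------------------------
# feature contributions


def _occurrences(sample: EncodedSample, feature: int) -> list[int]:
    return [vi for vi, (_d, toks) in enumerate(sample.visits) if feature in toks]


def _without_occurrence(sample: EncodedSample, feature: int, visit_idx: int) -> EncodedSample:
    visits = []
    for vi, (days, toks) in enumerate(sample.visits):
        if vi == visit_idx:
            toks = [t for t in toks if t != feature]
            if not toks:
                continue  # a visit emptied by the removal is dropped
        visits.append((days, list(toks)))
    return EncodedSample(sample.patient_id, sample.index_date, sample.label, visits)


def _to_scale(p: np.ndarray, fc_scale: str) -> np.ndarray:
    if fc_scale == "probability":
        return p
    q = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(q / (1.0 - q))


def compute_fc(
    model: SequenceClassifier, sample: EncodedSample, feature: int,
    fc_scale: str = "logit",
) -> float:
    """Removal-perturbation contribution of one feature in one sample.

    Raises if the feature does not occur in the sample's history.
    """
    occ = _occurrences(sample, feature)
    if not occ:
        raise ValueError(f"feature {feature} does not occur in the sample")
    variants = [_without_occurrence(sample, feature, vi) for vi in occ]
    scores = _to_scale(model.predict(variants + [sample]), fc_scale)
    base = scores[-1]
    return float(np.sum(base - scores[:-1]))


def fc_for_sample(
    model: SequenceClassifier, sample: EncodedSample, features: set[int],
    fc_scale: str = "logit",
) -> dict[int, float]:
    """FC of every requested feature occurring in the sample, one batched pass."""
    plan: list[tuple[int, EncodedSample]] = []
    for feat in features:
        for vi in _occurrences(sample, feat):
            plan.append((feat, _without_occurrence(sample, feat, vi)))
    if not plan:
        return {}
    scores = _to_scale(model.predict([s for _, s in plan] + [sample]), fc_scale)
    base = scores[-1]
    out: dict[int, float] = {}
    for (feat, _), sc in zip(plan, scores[:-1]):
        out[feat] = out.get(feat, 0.0) + float(base - sc)
    return out


def select_patient_samples(
    samples: list[EncodedSample], sample_mode: str = "closest"
) -> dict[str, list[EncodedSample]]:
    """One evaluation unit per patient.

    Case patients may carry several augmented samples; ``closest`` keeps the
    one anchored nearest the event (latest index date), ``mean`` keeps all
    and averages their FCs.
    """
    by_patient: dict[str, list[EncodedSample]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    out: dict[str, list[EncodedSample]] = {}
    for pid, group in by_patient.items():
        if sample_mode == "closest" and len(group) > 1:
            group = [max(group, key=lambda s: s.index_date)]
        out[pid] = group
    return out


def build_fc_table(
    model: SequenceClassifier,
    samples: list[EncodedSample],
    features: set[int],
    config: ContributionConfig | None = None,
) -> pd.DataFrame:
    """Per-(feature, patient) contributions split by event status.

    Returns a tidy frame with columns ``feature``, ``patient_id``, ``event``
    and ``fc`` — one row per carrier patient (``group_mode="carriers"``) or
    per patient with zero-filled non-carriers (``group_mode="all"``).
    """
    config = config or ContributionConfig()
    config.validate()
    rows = []
    units = select_patient_samples(samples, config.sample_mode)
    for pid, group in sorted(units.items()):
        event = group[0].label
        acc: dict[int, list[float]] = {}
        for s in group:
            for feat, fc in fc_for_sample(model, s, features, config.fc_scale).items():
                acc.setdefault(feat, []).append(fc)
        for feat, fcs in acc.items():
            rows.append((feat, pid, event, float(np.mean(fcs))))
        if config.group_mode == "all":
            for feat in features - set(acc):
                rows.append((feat, pid, event, 0.0))
    return pd.DataFrame(rows, columns=["feature", "patient_id", "event", "fc"])


# ---------------------------------------------------------------------------
# the RC statistic


def relative_contribution(fc_event: np.ndarray, fc_noevent: np.ndarray) -> float:
    """Ratio of group means: mean FC with event over mean FC without event.

    Defined for group means of matching sign (the ratio is then positive);
    protective features carry negative FC in both groups and still yield a
    valid RC < 1 when events bear the smaller burden.
    """
    m1, m0 = float(np.mean(fc_event)), float(np.mean(fc_noevent))
    if m1 * m0 <= 0:
        raise ValueError("group means must be nonzero and of matching sign")
    return m1 / m0


def variance_ln_rc(fc_event: np.ndarray, fc_noevent: np.ndarray) -> float:
    """Delta-method variance of ln RC from within-group CVs (sample sd)."""
    m, n = len(fc_event), len(fc_noevent)
    if m < 2 or n < 2:
        raise ValueError("both groups need >= 2 patients for a sample sd")
    cv1 = np.std(fc_event, ddof=1) / np.mean(fc_event)
    cv2 = np.std(fc_noevent, ddof=1) / np.mean(fc_noevent)
    return float(cv1 ** 2 / m + cv2 ** 2 / n)


def confidence_interval(rc: float, var: float, z: float = 1.96) -> tuple[float, float]:
    """Log-symmetric interval exp(ln RC +- z sqrt(var))."""
    if rc <= 0:
        raise ValueError("rc must be positive")
    if var < 0:
        raise ValueError("var must be non-negative")
    half = z * math.sqrt(var)
    return math.exp(math.log(rc) - half), math.exp(math.log(rc) + half)


def p_value(rc: float, var: float) -> float:
    """Two-sided normal tail probability of z = ln RC / sqrt(var)."""
    if var < 0:
        raise ValueError("var must be non-negative")
    if var == 0.0:
        if rc == 1.0:
            return 1.0
        logger.warning("p_value: zero variance with rc != 1 — degenerate, p = 0")
        return 0.0
    z = math.log(rc) / math.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def adjust(p_values) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p and Benjamini-Hochberg q over the tested set."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([])
    bonf = np.minimum(p * p.size, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return bonf, q


def ci_low_from_symmetry(rc: float, ci_high: float) -> float:
    """Lower bound implied by RC and the upper bound under log-symmetry.

    The interval of :func:`confidence_interval` satisfies
    ``low * high = rc**2``, so ``low = exp(2 ln rc - ln high)`` — useful as a
    consistency check on reported (RC, CI) triples.
    """
    return math.exp(2.0 * math.log(rc) - math.log(ci_high))


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (digits - 1))


# ---------------------------------------------------------------------------
# the full analysis


def analyze_contributions(
    fc_table: pd.DataFrame,
    config: ContributionConfig | None = None,
    feature_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RC statistics for every feature in an FC table.

    Returns ``(results, exclusions)``. ``results`` has one row per tested
    feature: rc, var_ln_rc, ci95_low/high, p_raw, p_bonferroni, q_fdr, m, n,
    direction and the significance flag (Bonferroni p < alpha and CI
    excluding 1). ``exclusions`` records features that failed the support or
    sign preconditions, with the reason — nothing is silently dropped.
    Bonferroni's N is the number of *tested* features (post-exclusion).
    """
    config = config or ContributionConfig()
    config.validate()
    tested, excluded = [], []
    for feat, grp in fc_table.groupby("feature", sort=True):
        fc1 = grp.loc[grp["event"] == 1, "fc"].to_numpy(dtype=float)
        fc0 = grp.loc[grp["event"] == 0, "fc"].to_numpy(dtype=float)
        m, n = len(fc1), len(fc0)
        # support is judged on carriers (non-zero rows) in either mode
        car1, car0 = int(np.count_nonzero(fc1)), int(np.count_nonzero(fc0))
        if car1 < config.min_support or car0 < config.min_support:
            excluded.append((feat, m, n, "insufficient-support"))
            continue
        mean1, mean0 = float(np.mean(fc1)), float(np.mean(fc0))
        if mean1 * mean0 <= 0:
            excluded.append((feat, m, n, "sign-invalid"))
            continue
        rc = relative_contribution(fc1, fc0)
        var = variance_ln_rc(fc1, fc0)
        lo, hi = confidence_interval(rc, var)
        tested.append({
            "feature": feat, "rc": rc, "var_ln_rc": var,
            "ci95_low": lo, "ci95_high": hi,
            "p_raw": p_value(rc, var), "m": m, "n": n,
        })
    exclusions = pd.DataFrame(excluded, columns=["feature", "m", "n", "reason"])
    if not tested:
        results = pd.DataFrame(columns=[
            "feature", "rc", "var_ln_rc", "ci95_low", "ci95_high", "p_raw",
            "p_bonferroni", "q_fdr", "m", "n", "direction", "significant",
        ])
        return results, exclusions
    results = pd.DataFrame(tested)
    bonf, q = adjust(results["p_raw"])
    results["p_bonferroni"] = bonf
    results["q_fdr"] = q
    results["direction"] = np.where(results["rc"] > 1.0, "risk", "protective")
    results["significant"] = (results["p_bonferroni"] < config.alpha) & (
        (results["ci95_low"] > 1.0) | (results["ci95_high"] < 1.0)
    )
    if feature_names:
        results.insert(1, "feature_name", results["feature"].map(feature_names))
        if len(exclusions):
            exclusions.insert(1, "feature_name", exclusions["feature"].map(feature_names))
    return results.sort_values("p_raw", kind="stable").reset_index(drop=True), exclusions


def significance_filter(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows passing the joint filter: Bonferroni p < alpha and CI excludes 1."""
    keep = (results["p_bonferroni"] < alpha) & (
        (results["ci95_low"] > 1.0) | (results["ci95_high"] < 1.0)
    )
    return results.loc[keep].reset_index(drop=True)
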