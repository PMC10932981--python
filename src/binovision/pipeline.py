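"""Orchestration: per-subject analysis, group analysis, and reporting.

``analyze_subject`` turns one subject's trial table into a summary:
detection and masking thresholds from 75%-correct logistic fits, the
two-stage gain-control fit (gains, weights, suppression strengths), the
balance point from the combination task, the 62.5% stereo threshold, and
the four sensory eye imbalances.

``analyze_group`` assembles the full between-group battery from two lists
of summaries: descriptive statistics, Mann–Whitney comparisons, the 2x3
stereo ANOVA with Bonferroni post hocs, Spearman correlation matrices of
the signed imbalances (per cohort and combined), absolute-imbalance vs
stereoacuity correlations, a Fisher r-to-z comparison of the
threshold-vs-weight imbalance correlation between groups, and
Wilcoxon–Mann–Whitney power for the three headline measures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .gain_control import (
    DEFAULT_CONSTANTS,
    FixedModelConstants,
    GainControlParams,
    ImbalanceSet,
    SuppressionStrength,
    ThresholdQuartet,
    fit_gain_control,
    sensory_imbalances,
    suppression_strength,
)
from .observer import TRIAL_COLUMNS, ProtocolConfig, DEFAULT_PROTOCOL
from .psychometrics import (
    BalancePointResult,
    fit_balance_point,
    fit_pf,
    threshold_from_fit,
)
from .stats import (
    fisher_compare,
    mann_whitney,
    spearman,
    two_way_anova,
    wmw_power,
)
from .units import log2_to_arcsec

__all__ = [
    "SubjectSummary",
    "GroupReport",
    "SCHEMA_VERSION",
    "analyze_subject",
    "analyze_group",
    "load_trials",
    "validate_trials",
    "simulate_and_analyze_cohorts",
    "group_effect_directions",
]

SCHEMA_VERSION = "1"

IMBALANCE_KEYS = [
    "threshold_imbalance",
    "fusion_imbalance",
    "weight_imbalance",
    "strength_imbalance",
]
STEREO_TESTS = ["4c", "titmus", "tno"]


@dataclass
class SubjectSummary:
    """Per-subject analysis output; missing tasks leave fields as NaN/None."""

    subject_id: str
    group: str
    det_thr_db_R: float = math.nan
    det_thr_db_L: float = math.nan
    mask_thr_db_R: float = math.nan  # target-in-right condition
    mask_thr_db_L: float = math.nan
    params: GainControlParams | None = None
    strength: SuppressionStrength | None = None
    balance: BalancePointResult | None = None
    stereo_log2: dict = field(default_factory=dict)  # test -> log2 arcsec
    imbalances: ImbalanceSet | None = None
    flags: list = field(default_factory=list)

    def measure(self, name: str) -> float:
        """Scalar per-subject value for a named group-level measure."""
        if name == "detection_threshold":
            return (self.det_thr_db_R + self.det_thr_db_L) / 2.0
        if name == "masking_weight":
            return (self.params.WR + self.params.WL) / 2.0 if self.params else math.nan
        if name == "masking_strength":
            return (
                (self.strength.supstrR + self.strength.supstrL) / 2.0
                if self.strength else math.nan
            )
        if name == "abs_balance_point":
            return abs(self.balance.bp) if self.balance else math.nan
        if name.startswith("stereo_"):
            return self.stereo_log2.get(name.removeprefix("stereo_"), math.nan)
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "subject_id": self.subject_id,
            "group": self.group,
            "det_thr_db_R": self.det_thr_db_R,
            "det_thr_db_L": self.det_thr_db_L,
            "mask_thr_db_R": self.mask_thr_db_R,
            "mask_thr_db_L": self.mask_thr_db_L,
            "gain_control": self.params.to_dict() if self.params else None,
            "balance_point_db": self.balance.bp if self.balance else None,
            "stereo_log2": self.stereo_log2,
            "stereo_arcsec": {
                k: log2_to_arcsec(v) for k, v in self.stereo_log2.items()
                if math.isfinite(v)
            },
            "imbalances": self.imbalances.to_dict() if self.imbalances else None,
            "flags": self.flags,
        }


def validate_trials(trials: pd.DataFrame, source: str = "<memory>") -> None:
    """Check the shared trial-table schema; raise with row context."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    lv = pd.to_numeric(trials["level"], errors="coerce")
    bad = trials.index[lv.isna()]
    if len(bad):
        raise ValueError(f"{source}: non-numeric 'level' at row {bad[0]}")
    ok = trials["outcome"].isin([0, 1, True, False])
    if not ok.all():
        row = trials.index[~ok][0]
        raise ValueError(
            f"{source}: field 'outcome' must be binary, bad value "
            f"{trials.loc[row, 'outcome']!r} at row {row}"
        )


def load_trials(path) -> pd.DataFrame:
    """Read a trial CSV in the shared schema, validating it."""
    trials = pd.read_csv(path)
    validate_trials(trials, source=str(path))
    return trials


def _task(trials: pd.DataFrame, task: str, condition: str | None = None) -> pd.DataFrame:
    sub = trials[trials["task"] == task]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    return sub


def analyze_subject(
    trials: pd.DataFrame,
    clinical_stereo: dict | None = None,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
    protocol: ProtocolConfig = DEFAULT_PROTOCOL,
) -> SubjectSummary:
    """Analyse one subject's trial bundle.

    ``clinical_stereo`` optionally supplies administered Titmus/TNO log2
    thresholds (these tests have no trial data).  Missing tasks produce a
    partial summary with an explanatory flag instead of failing.
    """
    validate_trials(trials)
    sid = str(trials["subject_id"].iloc[0]) if len(trials) else "unknown"
    group = str(trials["group"].iloc[0]) if len(trials) else "unknown"
    out = SubjectSummary(subject_id=sid, group=group)

    # detection thresholds (75% correct, rising PF in dB)
    det = {}
    for eye in ("R", "L"):
        sub = _task(trials, "detection", eye)
        if len(sub) == 0:
            out.flags.append(f"missing detection data for eye {eye}")
            continue
        fit = fit_pf(sub["level"], sub["outcome"], guess=0.5, slope_sign=+1)
        if not fit.converged:
            out.flags.append(f"detection fit non-convergent for eye {eye}")
            continue
        det[eye] = threshold_from_fit(fit.model, 0.75)
    out.det_thr_db_R = det.get("R", math.nan)
    out.det_thr_db_L = det.get("L", math.nan)

    # masking thresholds (75% correct, falling PF in mask dB)
    mask = {}
    for eye, cond in (("R", "target_R"), ("L", "target_L")):
        sub = _task(trials, "masking", cond)
        if len(sub) == 0:
            out.flags.append(f"missing masking data for condition {cond}")
            continue
        fit = fit_pf(sub["level"], sub["outcome"], guess=0.5, slope_sign=-1)
        if not fit.converged:
            out.flags.append(f"masking fit non-convergent for condition {cond}")
            continue
        mask[eye] = threshold_from_fit(fit.model, 0.75)
    out.mask_thr_db_R = mask.get("R", math.nan)
    out.mask_thr_db_L = mask.get("L", math.nan)

    # gain-control model fit (targets re-derived as detection + offset)
    if len(det) == 2 and len(mask) == 2:
        quartet = ThresholdQuartet.from_db(
            detR=det["R"], detL=det["L"], maskR=mask["R"], maskL=mask["L"],
            target_offset_db=protocol.target_offset_db,
        )
        try:
            out.params = fit_gain_control(quartet, consts)
            out.strength = suppression_strength(out.params)
            if not out.params.converged:
                out.flags.append("gain-control fit flagged non-convergent")
        except ValueError as err:
            out.flags.append(f"gain-control fit failed: {err}")
    else:
        out.flags.append("gain-control fit skipped: incomplete threshold quartet")

    # balance point
    comb = _task(trials, "combination")
    if len(comb):
        bp = fit_balance_point(comb["level"], comb["outcome"])
        out.balance = bp
        if not bp.converged:
            out.flags.append("balance-point fit non-convergent")
    else:
        out.flags.append("missing combination data")

    # stereo threshold (62.5% for 4AFC), crossed+uncrossed pooled
    st = _task(trials, "stereo")
    if len(st):
        fit = fit_pf(st["level"], st["outcome"], guess=0.25, slope_sign=+1)
        if fit.converged:
            out.stereo_log2["4c"] = threshold_from_fit(fit.model, 0.625)
        else:
            out.flags.append("stereo fit non-convergent")
    else:
        out.flags.append("missing stereo data")
    for test in ("titmus", "tno"):
        if clinical_stereo and test in clinical_stereo:
            out.stereo_log2[test] = float(clinical_stereo[test])

    if out.params is not None and out.balance is not None and len(det) == 2:
        out.imbalances = sensory_imbalances(
            det["R"], det["L"], out.params, out.balance.bp
        )
    return out


def simulate_and_analyze_cohorts(
    seed: int,
    aging=None,
    control=None,
) -> "GroupReport":
    """Simulate default aging+control cohorts and run the full analysis.

    Each cohort gets an independent RNG stream derived from ``seed``.
    Titmus/TNO values come from the generative ground truth (administered
    clinical tests, not trial simulations).
    """
    from .observer import (
        AGING_COHORT,
        CONTROL_COHORT,
        generate_cohort,
        make_observer,
        simulate_full_protocol,
    )

    cohorts = {"aging": aging or AGING_COHORT, "control": control or CONTROL_COHORT}
    summaries: dict[str, list[SubjectSummary]] = {}
    for stream, (label, cohort) in enumerate(cohorts.items()):
        rng = np.random.default_rng([seed, stream])
        specs, truth = generate_cohort(cohort, rng)
        ss = []
        for sp, sid in zip(specs, truth["subject_id"]):
            obs = make_observer(sp)
            trials = simulate_full_protocol(obs, rng)
            trials.insert(0, "subject_id", sid)
            trials.insert(1, "group", cohort.group)
            ss.append(
                analyze_subject(trials, clinical_stereo={
                    "titmus": sp.stereo_log2_titmus, "tno": sp.stereo_log2_tno})
            )
        summaries[label] = ss
    return analyze_group(summaries["aging"], summaries["control"])


def group_effect_directions(report: "GroupReport") -> dict[str, bool]:
    """Whether a simulated-study report shows the expected aging effects.

    Detection thresholds and masking weights: significantly higher in aging
    (Mann-Whitney, two-sided, alpha 0.05).  Stereoacuity: significant group
    effect in the 2x3 ANOVA with aging worse.  Suppression strength (lower
    in aging) and absolute balance point (higher in aging): direction only.
    """
    mw = report.mann_whitney
    d = report.descriptives
    ga, gb = report.groups
    return {
        "detection_sig_higher": mw["detection_threshold"]["p"] < 0.05
        and mw["detection_threshold"]["z"] > 0,
        "weight_sig_higher": mw["masking_weight"]["p"] < 0.05
        and mw["masking_weight"]["z"] > 0,
        "stereo_sig_worse": report.anova_stereo["effects"]["group"]["p"] < 0.05
        and d["stereo_4c"][ga]["mean"] > d["stereo_4c"][gb]["mean"],
        "strength_lower": d["masking_strength"][ga]["mean"]
        < d["masking_strength"][gb]["mean"],
        "abs_bp_higher": d["abs_balance_point"][ga]["mean"]
        > d["abs_balance_point"][gb]["mean"],
    }


MW_MEASURES = [
    "detection_threshold",
    "masking_weight",
    "masking_strength",
    "abs_balance_point",
    "stereo_4c",
    "stereo_titmus",
    "stereo_tno",
]


@dataclass
class GroupReport:
    """Machine-readable twin of a two-group results battery."""

    schema_version: str
    groups: tuple[str, str]
    n: dict
    descriptives: dict
    mann_whitney: dict
    anova_stereo: dict
    correlations: dict
    abs_imbalance_vs_stereo: dict
    fisher_comparisons: dict
    power: dict
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "groups": list(self.groups),
            "n": self.n,
            "descriptives": self.descriptives,
            "mann_whitney": self.mann_whitney,
            "anova_stereo": self.anova_stereo,
            "correlations": self.correlations,
            "abs_imbalance_vs_stereo": self.abs_imbalance_vs_stereo,
            "fisher_comparisons": self.fisher_comparisons,
            "power": self.power,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _imbalance_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        if s.imbalances is None:
            continue
        d = s.imbalances.to_dict()
        d["subject_id"] = s.subject_id
        for t in STEREO_TESTS:
            d[f"stereo_{t}"] = s.stereo_log2.get(t, math.nan)
        rows.append(d)
    return pd.DataFrame(rows)


def _corr_matrix(df: pd.DataFrame, keys: list[str]) -> dict:
    """Spearman matrix as nested dict {var: {var: {rho, p}}}."""
    out: dict = {}
    for a in keys:
        out[a] = {}
        for b in keys:
            if a == b:
                out[a][b] = {"rho": 1.0, "p": 0.0}
                continue
            sub = df[[a, b]].dropna()
            if len(sub) < 3:
                out[a][b] = {"rho": math.nan, "p": math.nan}
                continue
            r = spearman(sub[a], sub[b])
            out[a][b] = {"rho": r.rho, "p": r.p}
    return out


def analyze_group(
    summaries_a: Sequence[SubjectSummary],
    summaries_b: Sequence[SubjectSummary],
    power_alpha: float = 0.05,
) -> GroupReport:
    """Full between-group battery for two cohorts of subject summaries.

    The first cohort plays the role of the test group (e.g. aging), the
    second of the control group; Mann–Whitney Z values are signed for the
    first-minus-second ordering.
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    ga = summaries_a[0].group
    gb = summaries_b[0].group
    by_group = {ga: summaries_a, gb: summaries_b}

    descriptives: dict = {}
    mw: dict = {}
    for m in MW_MEASURES:
        vals = {
            g: np.array([s.measure(m) for s in ss], dtype=float)
            for g, ss in by_group.items()
        }
        vals = {g: v[np.isfinite(v)] for g, v in vals.items()}
        descriptives[m] = {
            g: {"mean": float(v.mean()) if len(v) else math.nan,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else math.nan,
                "n": int(len(v))}
            for g, v in vals.items()
        }
        if len(vals[ga]) >= 2 and len(vals[gb]) >= 2:
            mw[m] = mann_whitney(vals[ga], vals[gb], name=m).to_dict()

    # stereo ANOVA: group x test method on log2 thresholds
    long_rows = []
    for g, ss in by_group.items():
        for s in ss:
            for t in STEREO_TESTS:
                v = s.stereo_log2.get(t, math.nan)
                if math.isfinite(v):
                    long_rows.append((v, g, t))
    anova_dict: dict = {}
    if long_rows:
        v, fg, ft = zip(*long_rows)
        try:
            anova_dict = two_way_anova(v, fg, ft).to_dict()
        except ValueError as err:
            anova_dict = {"error": str(err)}

    # imbalance correlation matrices: combined, then per group
    frames = {g: _imbalance_frame(ss) for g, ss in by_group.items()}
    combined = pd.concat(frames.values(), ignore_index=True) if any(
        len(f) for f in frames.values()
    ) else pd.DataFrame()
    correlations = {
        "combined": _corr_matrix(combined, IMBALANCE_KEYS) if len(combined) else {},
        ga: _corr_matrix(frames[ga], IMBALANCE_KEYS) if len(frames[ga]) else {},
        gb: _corr_matrix(frames[gb], IMBALANCE_KEYS) if len(frames[gb]) else {},
    }
    abs_keys = [f"abs_{k}" for k in IMBALANCE_KEYS]
    stereo_keys = [f"stereo_{t}" for t in STEREO_TESTS]
    abs_vs_stereo = {}
    for label, frame in (("combined", combined), (ga, frames[ga]), (gb, frames[gb])):
        block: dict = {}
        for a in abs_keys:
            block[a] = {}
            for b in stereo_keys:
                if len(frame) == 0:
                    block[a][b] = {"rho": math.nan, "p": math.nan}
                    continue
                sub = frame[[a, b]].dropna()
                if len(sub) < 3:
                    block[a][b] = {"rho": math.nan, "p": math.nan}
                    continue
                r = spearman(sub[a], sub[b])
                block[a][b] = {"rho": r.rho, "p": r.p}
        abs_vs_stereo[label] = block

    # Fisher comparison of the threshold-vs-weight imbalance correlation
    fisher: dict = {}
    try:
        ra = correlations[ga]["threshold_imbalance"]["weight_imbalance"]["rho"]
        rb = correlations[gb]["threshold_imbalance"]["weight_imbalance"]["rho"]
        na = len(frames[ga].dropna(subset=["threshold_imbalance", "weight_imbalance"]))
        nb = len(frames[gb].dropna(subset=["threshold_imbalance", "weight_imbalance"]))
        if math.isfinite(ra) and math.isfinite(rb):
            z, p = fisher_compare(rb, nb, ra, na)  # control minus aging ordering
            fisher["threshold_vs_weight_imbalance"] = {
                "rho_" + ga: ra, "rho_" + gb: rb, "z": z, "p": p,
                "n_" + ga: na, "n_" + gb: nb,
            }
    except (KeyError, ValueError):
        pass

    # a priori WMW power for the three headline measures
    power = {}
    for m in ("detection_threshold", "masking_weight", "stereo_4c"):
        da, db_ = descriptives[m][ga], descriptives[m][gb]
        n = min(da["n"], db_["n"])
        if n >= 2 and da["sd"] > 0 and db_["sd"] > 0:
            power[m] = wmw_power(
                da["mean"], da["sd"], db_["mean"], db_["sd"], n, alpha=power_alpha
            )

    return GroupReport(
        schema_version=SCHEMA_VERSION,
        groups=(ga, gb),
        n={ga: len(summaries_a), gb: len(summaries_b)},
        descriptives=descriptives,
        mann_whitney=mw,
        anova_stereo=anova_dict,
        correlations=correlations,
        abs_imbalance_vs_stereo=abs_vs_stereo,
        fisher_comparisons=fisher,
        power=power,
        meta={"package_version": _pkg_version},
    )
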