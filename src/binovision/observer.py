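"""Simulated observers and cohorts for end-to-end pipeline exercise.

Each simulated observer is defined by the quantities the analysis is meant
to recover: per-eye detection thresholds (dB contrast), per-eye interocular
suppression weights (WR, WL in dB), a fusion balance point (dB), and a
stereoacuity (log2 arc seconds), plus psychometric slopes.  The observer's
internal gain-control parameters are obtained by inverting the two-stage
model (gain from the detection threshold, weight from its dB value), so
that the masking thresholds the observer produces are exactly the model's
predictions.  Trial-level responses are Bernoulli draws from logistic
psychometric functions anchored so that p(correct) equals the task's
criterion probability (75% or 62.5%) exactly at the implied threshold.

Cohort generators draw observer fields independently from group
distributions whose defaults are the aging/control summary statistics the
analysis pipeline is meant to reproduce in expectation: detection
-38.3 ± 3.6 dB (aging) vs -44.0 ± 3.6 dB (control); masking weights
-7.9 ± 3.6 vs -11.8 ± 2.3 dB; mean absolute balance point 2.8 vs 1.7 dB
(signed BP modelled half-normal); log2 stereoacuity 6.3 ± 1.0 vs 5.5 ± 0.7
for the four-circles test, with Titmus and TNO drawn around their own group
means sharing a common latent component per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import staircase as sc
from .gain_control import (
    DEFAULT_CONSTANTS,
    DegenerateMaskingError,
    FixedModelConstants,
    GainControlParams,
    mask_threshold,
    _stage1_unit_drive,
)
from .psychometrics import PsychometricModel, fit_pf, threshold_from_fit
from .units import db_to_percent, percent_to_db, ratio_to_db

__all__ = [
    "ObserverSpec",
    "CohortSpec",
    "ProtocolConfig",
    "SimulatedObserver",
    "make_observer",
    "generate_cohort",
    "simulate_full_protocol",
    "simulate_cohort_trials",
    "AGING_COHORT",
    "CONTROL_COHORT",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "task",
    "condition",
    "staircase_id",
    "trial_index",
    "level",
    "level_unit",
    "outcome",
]


@dataclass(frozen=True)
class ObserverSpec:
    """Generative ground truth for one simulated subject."""

    det_thr_db_R: float
    det_thr_db_L: float
    weight_db_R: float  # WR: suppression received by the right eye
    weight_db_L: float
    bp_db: float
    stereo_log2_4c: float
    stereo_log2_titmus: float
    stereo_log2_tno: float
    det_spread_db: float = 2.0
    mask_spread_db: float = 2.0
    bp_spread_db: float = 3.0
    stereo_spread_log2: float = 0.5
    lapse: float = 0.0

    def __post_init__(self) -> None:
        for name in ("det_spread_db", "mask_spread_db", "bp_spread_db", "stereo_spread_log2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")


@dataclass(frozen=True)
class ProtocolConfig:
    """Fixed experimental-protocol parameters shared by all subjects."""

    initial_target_db: float = -12.0
    initial_mask_db: float = -36.0
    target_offset_db: float = 9.0
    bp_base_contrast_pct: float = 45.0
    bp_ratios: tuple[float, ...] = (0.25, 0.5, 2.0**-0.5, 1.0, 2.0**0.5, 2.0, 4.0)
    bp_trials_per_ratio: int = 20
    stereo_initial_arcsec: float = 512.0
    n_repetitions: int = 2


DEFAULT_PROTOCOL = ProtocolConfig()


def _anchored_logistic(
    threshold: float, criterion: float, beta: float, gamma: float, lapse: float
) -> PsychometricModel:
    """Logistic model whose value at ``threshold`` is exactly ``criterion``."""
    ratio = (1.0 - gamma - lapse) / (criterion - gamma) - 1.0
    alpha = threshold + math.log(ratio) / beta
    return PsychometricModel(alpha=alpha, beta=beta, gamma=gamma, lapse=lapse)


class SimulatedObserver:
    """Response model for the four tasks, built by inverting the analysis.

    Detection and masking percent-correct follow logistics in dB anchored
    at the two-stage-model thresholds; combination reports follow a
    full-range logistic in ratio dB centred on the balance point; stereo
    follows a 4AFC logistic in log2 disparity.
    """

    def __init__(
        self,
        spec: ObserverSpec,
        consts: FixedModelConstants = DEFAULT_CONSTANTS,
        protocol: ProtocolConfig = DEFAULT_PROTOCOL,
    ) -> None:
        self.spec = spec
        self.consts = consts
        self.protocol = protocol
        xstar = _stage1_unit_drive(consts)
        det_pct_R = db_to_percent(spec.det_thr_db_R)
        det_pct_L = db_to_percent(spec.det_thr_db_L)
        self.params = GainControlParams(
            gR=xstar / det_pct_R,
            gL=xstar / det_pct_L,
            wR=10.0 ** (spec.weight_db_R / 20.0),
            wL=10.0 ** (spec.weight_db_L / 20.0),
        )
        off = protocol.target_offset_db
        self.target_db = {"R": spec.det_thr_db_R + off, "L": spec.det_thr_db_L + off}
        try:
            mask_pct_R = mask_threshold(
                self.params.gR, self.params.gL, self.params.wR,
                db_to_percent(self.target_db["R"]), consts,
            )
            mask_pct_L = mask_threshold(
                self.params.gL, self.params.gR, self.params.wL,
                db_to_percent(self.target_db["L"]), consts,
            )
        except DegenerateMaskingError as err:
            raise DegenerateMaskingError(
                f"observer spec implies degenerate masking: {err}"
            ) from err
        self.mask_thr_db = {"R": percent_to_db(mask_pct_R), "L": percent_to_db(mask_pct_L)}

        l = spec.lapse
        self._det_pf = {
            eye: _anchored_logistic(thr, 0.75, 1.0 / spec.det_spread_db, 0.5, l)
            for eye, thr in (("R", spec.det_thr_db_R), ("L", spec.det_thr_db_L))
        }
        self._mask_pf = {
            eye: _anchored_logistic(thr, 0.75, -1.0 / spec.mask_spread_db, 0.5, l)
            for eye, thr in self.mask_thr_db.items()
        }
        self._bp_pf = _anchored_logistic(spec.bp_db, 0.5, 1.0 / spec.bp_spread_db, 0.0, 0.0)
        self._stereo_pf = _anchored_logistic(
            spec.stereo_log2_4c, 0.625, 1.0 / spec.stereo_spread_log2, 0.25, l
        )

    def mask_pf_for_target(self, target_eye: str, target_db: float) -> PsychometricModel:
        """Masking psychometric function when the fixed target contrast is
        ``target_db`` (the experiment sets it from the *measured* detection
        threshold, so it may differ from the generative one)."""
        g_t, g_m, w = {
            "R": (self.params.gR, self.params.gL, self.params.wR),
            "L": (self.params.gL, self.params.gR, self.params.wL),
        }[target_eye]
        thr = percent_to_db(mask_threshold(g_t, g_m, w, db_to_percent(target_db), self.consts))
        return _anchored_logistic(
            thr, 0.75, -1.0 / self.spec.mask_spread_db, 0.5, self.spec.lapse
        )

    # response callbacks -------------------------------------------------
    def detect(self, eye: str, level_db: float, rng: np.random.Generator) -> bool:
        """Correctness of one monocular detection trial at ``level_db``."""
        return bool(rng.random() < self._det_pf[eye](level_db))

    def masked_detect(
        self,
        target_eye: str,
        mask_db: float,
        rng: np.random.Generator,
        pf: PsychometricModel | None = None,
    ) -> bool:
        """Correctness of one dichoptic-masking trial at mask level ``mask_db``."""
        pf = self._mask_pf[target_eye] if pf is None else pf
        return bool(rng.random() < pf(mask_db))

    def combination(self, ratio_db: float, rng: np.random.Generator) -> bool:
        """Whether the fused percept follows the left eye at this ratio."""
        return bool(rng.random() < self._bp_pf(ratio_db))

    def stereo(self, level_log2: float, rng: np.random.Generator) -> bool:
        """Correctness of one 4AFC stereo trial at log2 disparity."""
        return bool(rng.random() < self._stereo_pf(level_log2))


def make_observer(
    spec: ObserverSpec,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
    protocol: ProtocolConfig = DEFAULT_PROTOCOL,
) -> SimulatedObserver:
    """Build a responding observer from its generative spec."""
    return SimulatedObserver(spec, consts, protocol)


@dataclass(frozen=True)
class CohortSpec:
    """Group-level generative distribution for a cohort of observers.

    Per-eye fields (detection thresholds, weights) are drawn independently
    per eye; the signed balance point is Normal(0, sigma) with sigma chosen
    so the mean |BP| matches ``bp_abs_mean`` (half-normal identity
    E|X| = sigma * sqrt(2/pi)); stereo thresholds share a latent subject
    component across the three test types.
    """

    group: str
    n: int = 28
    det_mean: float = -38.3
    det_sd: float = 3.6
    weight_mean: float = -7.9
    weight_sd: float = 3.6
    bp_abs_mean: float = 2.8
    stereo_4c_mean: float = 6.3
    stereo_4c_sd: float = 1.0
    stereo_titmus_mean: float = 5.4
    stereo_titmus_sd: float = 0.8
    stereo_tno_mean: float = 7.1
    stereo_tno_sd: float = 1.1
    stereo_shared_frac: float = 0.6
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name in ("det_sd", "weight_sd", "stereo_4c_sd", "stereo_titmus_sd",
                     "stereo_tno_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.stereo_shared_frac <= 1.0:
            raise ValueError("stereo_shared_frac must be in [0, 1]")


AGING_COHORT = CohortSpec(group="aging")
CONTROL_COHORT = CohortSpec(
    group="control",
    det_mean=-44.0,
    det_sd=3.6,
    weight_mean=-11.8,
    weight_sd=2.3,
    bp_abs_mean=1.7,
    stereo_4c_mean=5.5,
    stereo_4c_sd=0.7,
    stereo_titmus_mean=5.0,
    stereo_titmus_sd=1.0,
    stereo_tno_mean=6.3,
    stereo_tno_sd=0.8,
)


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> tuple[list[ObserverSpec], pd.DataFrame]:
    """Draw a cohort of observer specs plus a ground-truth table."""
    rng = np.random.default_rng(rng)
    bp_sigma = spec.bp_abs_mean / math.sqrt(2.0 / math.pi)
    rows, specs = [], []
    a = math.sqrt(spec.stereo_shared_frac)
    b = math.sqrt(1.0 - spec.stereo_shared_frac)
    for i in range(spec.n):
        z_shared = rng.standard_normal()
        z = lambda: a * z_shared + b * rng.standard_normal()
        obs = ObserverSpec(
            det_thr_db_R=rng.normal(spec.det_mean, spec.det_sd),
            det_thr_db_L=rng.normal(spec.det_mean, spec.det_sd),
            weight_db_R=rng.normal(spec.weight_mean, spec.weight_sd),
            weight_db_L=rng.normal(spec.weight_mean, spec.weight_sd),
            bp_db=rng.normal(0.0, bp_sigma),
            stereo_log2_4c=spec.stereo_4c_mean + spec.stereo_4c_sd * z(),
            stereo_log2_titmus=spec.stereo_titmus_mean + spec.stereo_titmus_sd * z(),
            stereo_log2_tno=spec.stereo_tno_mean + spec.stereo_tno_sd * z(),
            lapse=spec.lapse,
        )
        specs.append(obs)
        rows.append(
            {
                "subject_id": f"{spec.group}_{i:03d}",
                "group": spec.group,
                "det_thr_db_R": obs.det_thr_db_R,
                "det_thr_db_L": obs.det_thr_db_L,
                "weight_db_R": obs.weight_db_R,
                "weight_db_L": obs.weight_db_L,
                "bp_db": obs.bp_db,
                "stereo_log2_4c": obs.stereo_log2_4c,
                "stereo_log2_titmus": obs.stereo_log2_titmus,
                "stereo_log2_tno": obs.stereo_log2_tno,
            }
        )
    return specs, pd.DataFrame(rows)


def _staircase_pair_trials(
    configs, responders, conditions, task, rep, rng, level_unit
):
    """Run an interleaved staircase pair and return trial rows."""
    pair = [sc.Staircase(c) for c in configs]
    sc.interleave(pair, responders, rng)
    rows = []
    for cond, stair in zip(conditions, pair):
        sid = f"{task}:{cond}:rep{rep}"
        for t, (lvl, out) in enumerate(zip(stair.levels, stair.outcomes)):
            rows.append((task, cond, sid, t, lvl, level_unit, int(out)))
    return rows


def simulate_full_protocol(
    observer: SimulatedObserver, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Simulate the complete four-task session for one observer.

    Order follows the experimental protocol: the monocular detection
    staircases are run first and their fitted thresholds (computed exactly
    as the analysis computes them) set the fixed masking target contrasts
    at +9 dB; then masking, binocular combination (7 ratios x 20 trials per
    repetition), and the stereo staircase pair (crossed/uncrossed).  Every
    task is repeated twice and all trials are returned in the shared
    trial-table schema (without subject/group columns).
    """
    rng = np.random.default_rng(rng)
    proto = observer.protocol
    rows: list[tuple] = []

    # --- monocular detection ------------------------------------------
    for rep in range(proto.n_repetitions):
        rows += _staircase_pair_trials(
            [sc.detection_config(proto.initial_target_db)] * 2,
            [lambda lvl, e="R": observer.detect(e, lvl, rng),
             lambda lvl, e="L": observer.detect(e, lvl, rng)],
            ["R", "L"], "detection", rep, rng, "dB",
        )

    # --- dichoptic masking (sideways: mask contrast varies) ------------
    # The protocol fixes each masking target at the measured detection
    # threshold + 9 dB; measure it the same way the analysis will.
    det_est: dict[str, float] = {}
    det_rows = [r for r in rows if r[0] == "detection"]
    for eye, true_thr in (("R", observer.spec.det_thr_db_R),
                          ("L", observer.spec.det_thr_db_L)):
        lv = [r[4] for r in det_rows if r[1] == eye]
        oc = [r[6] for r in det_rows if r[1] == eye]
        fit = fit_pf(lv, oc, guess=0.5, slope_sign=+1)
        det_est[eye] = (
            threshold_from_fit(fit.model, 0.75) if fit.converged else true_thr
        )
    mask_pfs = {}
    for e in ("R", "L"):
        try:
            mask_pfs[e] = observer.mask_pf_for_target(
                e, det_est[e] + proto.target_offset_db
            )
        except DegenerateMaskingError:
            # a grossly under-estimated detection threshold can imply a
            # sub-threshold masking target; the session still runs, so fall
            # back to the generative-truth masking function
            mask_pfs[e] = observer._mask_pf[e]
    for rep in range(proto.n_repetitions):
        rows += _staircase_pair_trials(
            [sc.masking_config(proto.initial_mask_db)] * 2,
            [lambda lvl, e="R": observer.masked_detect(e, lvl, rng, mask_pfs[e]),
             lambda lvl, e="L": observer.masked_detect(e, lvl, rng, mask_pfs[e])],
            ["target_R", "target_L"], "masking", rep, rng, "dB",
        )

    # --- binocular orientation combination ----------------------------
    ratios_db = [ratio_to_db(r) for r in proto.bp_ratios]
    for rep in range(proto.n_repetitions):
        schedule = np.repeat(np.arange(len(ratios_db)), proto.bp_trials_per_ratio)
        rng.shuffle(schedule)
        for t, idx in enumerate(schedule):
            lvl = ratios_db[idx]
            out = observer.combination(lvl, rng)
            rows.append(
                ("combination", "binocular", f"combination:rep{rep}", t, lvl,
                 "dB_ratio", int(out))
            )

    # --- 4AFC stereo ----------------------------------------------------
    for rep in range(proto.n_repetitions):
        rows += _staircase_pair_trials(
            [sc.stereo_config(proto.stereo_initial_arcsec)] * 2,
            [lambda lvl: observer.stereo(lvl, rng)] * 2,
            ["crossed", "uncrossed"], "stereo", rep, rng, "log2_arcsec",
        )

    return pd.DataFrame(
        rows,
        columns=["task", "condition", "staircase_id", "trial_index", "level",
                 "level_unit", "outcome"],
    )


def simulate_cohort_trials(
    cohort: CohortSpec,
    rng: np.random.Generator | int | None = None,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
    protocol: ProtocolConfig = DEFAULT_PROTOCOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate trial data for a whole cohort.

    Returns (trials, truth): the trial table in the shared CSV schema and
    the ground-truth table, which also serves as the source of the
    "clinical" Titmus/TNO stereo values (administered, not simulated).
    """
    rng = np.random.default_rng(rng)
    specs, truth = generate_cohort(cohort, rng)
    frames = []
    for spec_i, sid in zip(specs, truth["subject_id"]):
        obs = make_observer(spec_i, consts, protocol)
        df = simulate_full_protocol(obs, rng)
        df.insert(0, "subject_id", sid)
        df.insert(1, "group", cohort.group)
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return trials, truth
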