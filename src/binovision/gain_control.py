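"""Two-stage interocular gain-control model of dichoptic masking.

The model describes detection of a monocular grating target in the presence
of a contralateral noise mask with two stages of contrast gain control, one
before and one after binocular combination.  For a target in the right eye
with contrast ``c_T`` and a mask in the left eye with contrast ``c_M`` (both
in **percent** contrast units, 0–100):

    stage 1:  respR = (gR * c_T)**m / (S + gR * c_T + wR * gL * c_M)
    stage 2:  resp  = respR**p / (Z + respR**q)

``gR, gL`` are per-eye input gains and ``wR, wL`` interocular suppression
weights indexed by the *receiving* (target) eye: ``wR`` is the weight of the
suppression the right-eye target receives from the left-eye mask.  The
exponents ``m, p, q`` and saturation constants ``S, Z`` are fixed.  Assuming
internal response noise of unit standard deviation, a threshold is the
stimulus contrast at which ``resp == 1``.

Detection thresholds constrain the gains; "sideways" masking thresholds
(target fixed suprathreshold, mask contrast varied) constrain the weights.
With four observed thresholds and four free parameters the fit is exactly
determined and a nested closed-form solution exists; the simplex fit is
initialised from it and must agree with it on noiseless data.

Derived quantities: dB forms ``GR = 20*log10(gR)`` (likewise GL, WR, WL),
net suppression strengths ``supstrR = GL + WR`` / ``supstrL = GR + WL``, and
the four sensory eye imbalances (right minus left throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import optimize

from .units import percent_to_db

__all__ = [
    "FixedModelConstants",
    "GainControlParams",
    "ThresholdQuartet",
    "SuppressionStrength",
    "ImbalanceSet",
    "DegenerateMaskingError",
    "stage1_response",
    "stage2_response",
    "binocular_response",
    "stage2_unit_root",
    "detection_threshold",
    "mask_threshold",
    "predict_quartet",
    "closed_form_fit",
    "fit_gain_control",
    "suppression_strength",
    "sensory_imbalances",
]


def _lin_to_db(v: float) -> float:
    return 20.0 * math.log10(v)


class DegenerateMaskingError(ValueError):
    """The fixed target is at or below its own threshold: no positive mask
    contrast can bring the response down to criterion."""


@dataclass(frozen=True)
class FixedModelConstants:
    """Fixed (non-fitted) model constants.

    m: stage-1 excitation exponent; p, q: stage-2 numerator/denominator
    exponents (p > q keeps stage 2 monotone increasing); S, Z: stage-1/2
    saturation constants.
    """

    m: float = 1.3
    p: float = 8.0
    q: float = 6.6
    S: float = 1.0
    Z: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise ValueError(f"constant {f.name} must be positive")
        if not self.p > self.q:
            raise ValueError("need p > q for stage-2 monotonicity")


DEFAULT_CONSTANTS = FixedModelConstants()

_UNIT_ROOT_CACHE: dict[FixedModelConstants, float] = {}
_STAGE1_ROOT_CACHE: dict[FixedModelConstants, float] = {}


def stage1_response(
    c_target: float,
    c_mask: float,
    g_target: float,
    g_mask: float,
    w_received: float,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Monocular (stage-1) response to a target with a contralateral mask."""
    if c_target < 0 or c_mask < 0:
        raise ValueError("contrasts must be non-negative")
    if not (g_target > 0 and g_mask > 0 and w_received > 0):
        raise ValueError("gains and weights must be positive")
    e = g_target * c_target
    return e**consts.m / (consts.S + e + w_received * g_mask * c_mask)


def stage2_response(respR: float, consts: FixedModelConstants = DEFAULT_CONSTANTS) -> float:
    """Binocular (stage-2) response given the stage-1 output."""
    if respR < 0:
        raise ValueError("stage-1 response must be non-negative")
    return respR**consts.p / (consts.Z + respR**consts.q)


def binocular_response(
    c_target: float,
    c_mask: float,
    g_target: float,
    g_mask: float,
    w_received: float,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """stage2∘stage1: full model response to a target/mask arrangement."""
    return stage2_response(
        stage1_response(c_target, c_mask, g_target, g_mask, w_received, consts), consts
    )


def _bisect(f, lo: float, hi: float, tol: float = 1e-12, maxit: int = 200) -> float:
    flo = f(lo)
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0 or hi - lo < tol:
            return mid
        if (fm < 0) == (flo < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stage2_unit_root(consts: FixedModelConstants = DEFAULT_CONSTANTS) -> float:
    """The stage-1 response r* at which stage 2 outputs exactly 1.

    Solves ``r**p = Z + r**q`` by bracketed bisection; cached per constants.
    For the default constants r* lies just above 1.2.
    """
    if consts in _UNIT_ROOT_CACHE:
        return _UNIT_ROOT_CACHE[consts]
    f = lambda r: r**consts.p - consts.Z - r**consts.q
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
    root = _bisect(f, 1e-6, hi)
    _UNIT_ROOT_CACHE[consts] = root
    return root


def _stage1_unit_drive(consts: FixedModelConstants) -> float:
    """The effective drive x* = g*c solving x**m / (S + x) = r* (no mask)."""
    if consts in _STAGE1_ROOT_CACHE:
        return _STAGE1_ROOT_CACHE[consts]
    rstar = stage2_unit_root(consts)
    f = lambda x: x**consts.m / (consts.S + x) - rstar
    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
    root = _bisect(f, 1e-9, hi)
    _STAGE1_ROOT_CACHE[consts] = root
    return root


def detection_threshold(g: float, consts: FixedModelConstants = DEFAULT_CONSTANTS) -> float:
    """Unmasked detection threshold (percent contrast) for input gain ``g``.

    The threshold satisfies ``resp == 1`` with no mask; since contrast enters
    only through ``g*c`` it is exactly ``x*/g`` with x* the unit-response
    drive, hence proportional to 1/g.
    """
    if not g > 0:
        raise ValueError("gain must be positive")
    return _stage1_unit_drive(consts) / g


def mask_threshold(
    g_target: float,
    g_mask: float,
    w_received: float,
    c_target_fixed: float,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Sideways masking threshold: the mask contrast (percent) at which a
    fixed suprathreshold target falls back to ``resp == 1``.

    Closed form: with drive ``e = g_target*c_target`` and unit root r*,
    ``c_mask = (e**m / r* - S - e) / (w_received * g_mask)``.  If the
    numerator is not positive the target is at or below its own threshold
    and no positive mask threshold exists.
    """
    if not (g_target > 0 and g_mask > 0 and w_received > 0):
        raise ValueError("gains and weights must be positive")
    if not c_target_fixed > 0:
        raise ValueError("fixed target contrast must be positive")
    rstar = stage2_unit_root(consts)
    e = g_target * c_target_fixed
    num = e**consts.m / rstar - consts.S - e
    if num <= 0:
        raise DegenerateMaskingError(
            "fixed target contrast is at or below its own detection threshold; "
            "no positive mask contrast reduces the response to criterion"
        )
    return num / (w_received * g_mask)


@dataclass(frozen=True)
class GainControlParams:
    """Fitted per-subject model state: linear gains/weights and dB forms."""

    gR: float
    gL: float
    wR: float
    wL: float
    converged: bool = True
    rmse_db: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gR", "gL", "wR", "wL"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def GR(self) -> float:
        return _lin_to_db(self.gR)

    @property
    def GL(self) -> float:
        return _lin_to_db(self.gL)

    @property
    def WR(self) -> float:
        return _lin_to_db(self.wR)

    @property
    def WL(self) -> float:
        return _lin_to_db(self.wL)

    @classmethod
    def from_db(cls, GR: float, GL: float, WR: float, WL: float, **kw) -> "GainControlParams":
        f = lambda d: 10.0 ** (d / 20.0)
        return cls(gR=f(GR), gL=f(GL), wR=f(WR), wL=f(WL), **kw)

    def to_dict(self, consts: FixedModelConstants = DEFAULT_CONSTANTS) -> dict:
        s = suppression_strength(self)
        return {
            "m": consts.m,
            "p": consts.p,
            "q": consts.q,
            "S": consts.S,
            "Z": consts.Z,
            "gR": self.gR,
            "gL": self.gL,
            "wR": self.wR,
            "wL": self.wL,
            "GR": self.GR,
            "GL": self.GL,
            "WR": self.WR,
            "WL": self.WL,
            "supstrR": s.supstrR,
            "supstrL": s.supstrL,
        }


@dataclass(frozen=True)
class ThresholdQuartet:
    """The per-subject data the model is fitted to, in percent contrast.

    detR/detL: monocular detection thresholds; maskR/maskL: mask-contrast
    thresholds for the target-in-right / target-in-left conditions;
    targR/targL: the fixed suprathreshold target contrasts used in masking
    (protocol: detection threshold raised by +9 dB).
    """

    detR: float
    detL: float
    maskR: float
    maskL: float
    targR: float
    targL: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0 < v <= 100.0:
                raise ValueError(f"{f.name} must be a percent contrast in (0, 100], got {v!r}")

    @classmethod
    def from_db(cls, detR, detL, maskR, maskL, targR=None, targL=None, target_offset_db=9.0):
        """Build from dB thresholds; targets default to detection + offset."""
        if targR is None:
            targR = detR + target_offset_db
        if targL is None:
            targL = detL + target_offset_db
        f = lambda d: 100.0 * 10.0 ** (d / 20.0)
        return cls(f(detR), f(detL), f(maskR), f(maskL), f(targR), f(targL))


def predict_quartet(
    params: GainControlParams,
    targR: float,
    targL: float,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, float, float]:
    """Model-predicted (detR, detL, maskR, maskL) percent thresholds."""
    return (
        detection_threshold(params.gR, consts),
        detection_threshold(params.gL, consts),
        mask_threshold(params.gR, params.gL, params.wR, targR, consts),
        mask_threshold(params.gL, params.gR, params.wL, targL, consts),
    )


def closed_form_fit(
    data: ThresholdQuartet, consts: FixedModelConstants = DEFAULT_CONSTANTS
) -> GainControlParams:
    """Sequential exact solution: gains from the detection thresholds, then
    weights from the mask-threshold closed form.  With four data and four
    parameters this zeroes the residual whenever the quartet is attainable."""
    xstar = _stage1_unit_drive(consts)
    rstar = stage2_unit_root(consts)
    gR = xstar / data.detR
    gL = xstar / data.detL

    def weight(g_t: float, g_m: float, targ: float, mask_obs: float) -> float:
        e = g_t * targ
        num = e**consts.m / rstar - consts.S - e
        if num <= 0:
            raise DegenerateMaskingError(
                "fixed target at or below its own threshold; weights undefined"
            )
        return num / (g_m * mask_obs)

    wR = weight(gR, gL, data.targR, data.maskR)
    wL = weight(gL, gR, data.targL, data.maskL)
    return GainControlParams(gR=gR, gL=gL, wR=wR, wL=wL)


def _quartet_rmse_db(params: GainControlParams, data: ThresholdQuartet, consts) -> float:
    pred = predict_quartet(params, data.targR, data.targL, consts)
    obs = (data.detR, data.detL, data.maskR, data.maskL)
    resid = [percent_to_db(p) - percent_to_db(o) for p, o in zip(pred, obs)]
    return math.sqrt(sum(r * r for r in resid) / 4.0)


def fit_gain_control(
    data: ThresholdQuartet,
    consts: FixedModelConstants = DEFAULT_CONSTANTS,
    n_starts: int = 5,
    seed: int | None = 0,
) -> GainControlParams:
    """Fit (gR, gL, wR, wL) by minimising the RMS error between model and
    observed thresholds in dB.

    A derivative-free simplex search runs over log-parameters (which keeps
    the gains and weights positive) from multiple starts around the
    closed-form solution; the best minimum is returned.  On model-generated
    quartets this reproduces the closed form to well below 0.01 dB.
    """
    init = closed_form_fit(data, consts)
    x0 = np.log([init.gR, init.gL, init.wR, init.wL])

    def objective(x: np.ndarray) -> float:
        g = np.exp(x)
        try:
            p = GainControlParams(gR=g[0], gL=g[1], wR=g[2], wL=g[3])
            return _quartet_rmse_db(p, data, consts)
        except (DegenerateMaskingError, ValueError, OverflowError):
            return 1e6

    rng = np.random.default_rng(seed)
    best_x, best_f = x0, objective(x0)
    any_success = False

    def polish(start):
        nonlocal best_x, best_f, any_success
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11},
        )
        any_success = any_success or res.success
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun

    polish(x0)
    # the RMSE objective is non-negative, so a (near-)zero residual from the
    # closed-form start is already the global minimum; otherwise escalate to
    # perturbed restarts around it
    if best_f > 1e-8:
        for _ in range(max(0, n_starts - 1)):
            polish(x0 + rng.normal(scale=0.2, size=4))
    g = np.exp(best_x)
    return GainControlParams(
        gR=g[0], gL=g[1], wR=g[2], wL=g[3], converged=bool(any_success), rmse_db=float(best_f)
    )


@dataclass(frozen=True)
class SuppressionStrength:
    """Net interocular suppression received by each eye, in dB."""

    supstrR: float
    supstrL: float


def suppression_strength(params: GainControlParams) -> SuppressionStrength:
    """Net suppression: contralateral gain plus received weight (dB sums),
    ``supstrR = GL + WR`` and ``supstrL = GR + WL``."""
    return SuppressionStrength(
        supstrR=params.GL + params.WR, supstrL=params.GR + params.WL
    )


@dataclass(frozen=True)
class ImbalanceSet:
    """Sensory eye imbalances, all in dB with a right-minus-left sign
    convention (fusion imbalance keeps the balance point's own sign
    convention: positive = left dominant)."""

    threshold_imbalance: float
    fusion_imbalance: float
    weight_imbalance: float
    strength_imbalance: float

    @property
    def abs_threshold_imbalance(self) -> float:
        return abs(self.threshold_imbalance)

    @property
    def abs_fusion_imbalance(self) -> float:
        return abs(self.fusion_imbalance)

    @property
    def abs_weight_imbalance(self) -> float:
        return abs(self.weight_imbalance)

    @property
    def abs_strength_imbalance(self) -> float:
        return abs(self.strength_imbalance)

    def to_dict(self) -> dict:
        return {
            "threshold_imbalance": self.threshold_imbalance,
            "fusion_imbalance": self.fusion_imbalance,
            "weight_imbalance": self.weight_imbalance,
            "strength_imbalance": self.strength_imbalance,
            "abs_threshold_imbalance": self.abs_threshold_imbalance,
            "abs_fusion_imbalance": self.abs_fusion_imbalance,
            "abs_weight_imbalance": self.abs_weight_imbalance,
            "abs_strength_imbalance": self.abs_strength_imbalance,
        }


def sensory_imbalances(
    detR_dB: float, detL_dB: float, params: GainControlParams, balance_point: float
) -> ImbalanceSet:
    """The four interocular imbalances (dB): detection-threshold difference,
    fusion balance point, weight difference WR−WL, and strength difference
    supstrR−supstrL = (GL+WR)−(GR+WL)."""
    s = suppression_strength(params)
    return ImbalanceSet(
        threshold_imbalance=detR_dB - detL_dB,
        fusion_imbalance=balance_point,
        weight_imbalance=params.WR - params.WL,
        strength_imbalance=s.supstrR - s.supstrL,
    )
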