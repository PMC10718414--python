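"""Cue-weight analysis for the voice-gender categorisation task.

The manipulations are first mapped onto dimensionless normalised cues

    dF0 = -ΔF0/12 - 0.5        dVTL = ΔVTL/3.6 - 0.5

so that the female reference voice sits at (-0.5, -0.5) and the extreme
male-typical condition (ΔF0 = -12 st, ΔVTL = +3.6 st) at (+0.5, +0.5),
making the two cues functionally equivalent: each spans one unit across its
manipulation range (12 st of F0, 3.6 st of VTL).

Responses (male = 1, female = 0) are then fit with a mixed-effects logistic
regression: population-level intercept and slopes for dF0 and dVTL, plus
participant-level slope deviations for both cues. The logit slopes — natural
-log odds per unit of normalised cue — are converted to Berkson units (log2
odds) per semitone by dividing by ln(2) times the semitone span of the unit
interval:

    weight [Bk/st] = coef / (ln 2 * span_st),  span_st = 12 (F0) or 3.6 (VTL)

so a weight of w Bk/st means one semitone of that cue multiplies the odds of
a "male" categorisation by 2**w. Intercepts are reported both at the grid
midpoint delta = (0, 0) and re-expressed at the reference voice
(-0.5, -0.5), where they measure the bias toward hearing the unmodified
voice as female.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .manipulation import VoiceManipulation

__all__ = [
    "F0_SPAN_ST",
    "VTL_SPAN_ST",
    "NormalizedCue",
    "CueWeightFit",
    "SeparationError",
    "normalize_cues",
    "denormalize_cues",
    "to_berkson_per_st",
    "fit_cue_weights",
]

F0_SPAN_ST = 12.0   # semitone span of the normalised F0 unit interval
VTL_SPAN_ST = 3.6   # semitone span of the normalised VTL unit interval
LN2 = math.log(2.0)


class SeparationError(RuntimeError):
    """Raised when even the penalised fallback cannot produce a finite fit."""


@dataclass(frozen=True)
class NormalizedCue:
    dF0_norm: float
    dVTL_norm: float


def normalize_cues(manip: VoiceManipulation) -> NormalizedCue:
    """Map (ΔF0, ΔVTL) in semitones to the normalised (dF0, dVTL) cues."""
    return NormalizedCue(
        dF0_norm=-manip.delta_f0_st / F0_SPAN_ST - 0.5,
        dVTL_norm=manip.delta_vtl_st / VTL_SPAN_ST - 0.5,
    )


def denormalize_cues(cue: NormalizedCue) -> VoiceManipulation:
    """Exact affine inverse of ``normalize_cues``."""
    return VoiceManipulation(
        delta_f0_st=-(cue.dF0_norm + 0.5) * F0_SPAN_ST,
        delta_vtl_st=(cue.dVTL_norm + 0.5) * VTL_SPAN_ST,
    )


def to_berkson_per_st(coef_logit: float, cue: str) -> float:
    """Convert a logit slope (per unit normalised cue) to Berkson units per semitone."""
    if not np.isfinite(coef_logit):
        raise ValueError("coefficient must be finite")
    if cue == "F0":
        span = F0_SPAN_ST
    elif cue == "VTL":
        span = VTL_SPAN_ST
    else:
        raise ValueError("cue must be 'F0' or 'VTL'")
    return float(coef_logit) / (LN2 * span)


@dataclass(frozen=True)
class CueWeightFit:
    """Population coefficients, Berkson conversions, and per-participant table."""

    intercept_logit: float
    coef_f0_logit: float
    coef_vtl_logit: float
    weight_f0_bk_per_st: float
    weight_vtl_bk_per_st: float
    per_participant: pd.DataFrame
    method: str
    separation_flag: bool = False
    n_trials: int = 0
    n_participants: int = 0

    @property
    def intercept_at_reference(self) -> float:
        """Log-odds of 'male' for the unmodified reference voice (delta = (-0.5, -0.5))."""
        return self.intercept_logit - 0.5 * self.coef_f0_logit - 0.5 * self.coef_vtl_logit

    def to_dict(self) -> dict:
        return {
            "intercept_logit": self.intercept_logit,
            "intercept_at_reference": self.intercept_at_reference,
            "coef_f0_logit": self.coef_f0_logit,
            "coef_vtl_logit": self.coef_vtl_logit,
            "weight_f0_bk_per_st": self.weight_f0_bk_per_st,
            "weight_vtl_bk_per_st": self.weight_vtl_bk_per_st,
            "method": self.method,
            "separation_flag": self.separation_flag,
            "n_trials": self.n_trials,
            "n_participants": self.n_participants,
        }


def _design(trials: pd.DataFrame):
    required = {"participant_id", "dF0_norm", "dVTL_norm", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    y = (trials["response"].astype(str) == "male").to_numpy(dtype=float)
    x_f0 = trials["dF0_norm"].to_numpy(dtype=float)
    x_vtl = trials["dVTL_norm"].to_numpy(dtype=float)
    pids = pd.Categorical(trials["participant_id"])
    if len(pids.categories) < 2:
        raise ValueError("need at least 2 participants")
    for name, x in (("dF0_norm", x_f0), ("dVTL_norm", x_vtl)):
        if np.unique(x).size < 2:
            raise ValueError(f"rank-deficient design: {name} has a single level")
    X = np.column_stack([np.ones(y.size), x_f0, x_vtl])
    return y, X, x_f0, x_vtl, pids


def _penalized_logit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Weakly ridge-penalised logistic fit used when the MLE separates."""
    from sklearn.linear_model import LogisticRegression

    if y.min() == y.max():
        # one response category only: slopes are unidentified, report a
        # smoothed intercept (add-half rate) and zero slopes
        rate = (y.sum() + 0.5) / (y.size + 1.0)
        return np.array([math.log(rate / (1.0 - rate)), 0.0, 0.0])
    clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=1000)
    clf.fit(X[:, 1:], y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    if not np.all(np.isfinite(params)):
        raise SeparationError("penalised fallback produced non-finite coefficients")
    return params


def _pooled_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood pooled logit with separation detection/fallback."""
    if y.min() == y.max():
        return _penalized_logit(y, X), True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 30.0:
            return _penalized_logit(y, X), True
        return params, False
    except Exception:
        return _penalized_logit(y, X), True


def fit_cue_weights(trials: pd.DataFrame, method: str = "mixed") -> CueWeightFit:
    """Fit the cue-weight model to a categorisation trial table.

    ``trials`` needs columns participant_id, dF0_norm, dVTL_norm, response
    ('male'/'female'). Methods:

    * ``"mixed"`` (primary): population intercept + slopes with
      participant-level random slope deviations for both cues, fit by the
      variational-Bayes binomial mixed GLM; deterministic given the data.
    * ``"pooled"``: plain logistic regression ignoring participant structure.
    * ``"two_stage"``: per-participant logistic fits aggregated by their mean
      (weakly penalised, robust to per-participant separation).

    Degenerate one-sided data trigger a weakly penalised fallback and set
    ``separation_flag``.
    """
    y, X, x_f0, x_vtl, pids = _design(trials)
    categories = list(pids.categories)
    n_p = len(categories)
    codes = np.asarray(pids.codes)
    separation = False

    if method == "mixed":
        if y.min() == y.max():
            pop, separation = _pooled_logit(y, X)
            re_f0 = np.zeros(n_p)
            re_vtl = np.zeros(n_p)
            used = "pooled-penalized"
        else:
            Z = np.zeros((y.size, 2 * n_p))
            for j in range(n_p):
                mask = codes == j
                Z[mask, j] = x_f0[mask]
                Z[mask, n_p + j] = x_vtl[mask]
            ident = np.array([0] * n_p + [1] * n_p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM(y, X, Z, ident, vcp_p=2.0, fe_p=2.0)
                # explicit start point: the library default draws a random one
                n_par = model.k_fep + model.k_vcp + model.k_vc
                res = model.fit_vb(mean=np.zeros(n_par), sd=np.full(n_par, math.exp(-0.5)))
            pop = np.asarray(res.fe_mean)
            re_f0 = np.asarray(res.vc_mean[:n_p])
            re_vtl = np.asarray(res.vc_mean[n_p:])
            used = "mixed"
        per = pd.DataFrame(
            {
                "participant_id": categories,
                "intercept_logit": np.full(n_p, pop[0]),
                "coef_f0_logit": pop[1] + re_f0,
                "coef_vtl_logit": pop[2] + re_vtl,
            }
        )
    elif method == "pooled":
        pop, separation = _pooled_logit(y, X)
        per = pd.DataFrame(
            {
                "participant_id": categories,
                "intercept_logit": np.full(n_p, pop[0]),
                "coef_f0_logit": np.full(n_p, pop[1]),
                "coef_vtl_logit": np.full(n_p, pop[2]),
            }
        )
        used = "pooled-penalized" if separation else "pooled"
    elif method == "two_stage":
        rows = []
        for j, pid in enumerate(categories):
            mask = codes == j
            params = _penalized_logit(y[mask], X[mask]) if y[mask].min() == y[mask].max() else None
            if params is None:
                params, sep_j = _pooled_logit(y[mask], X[mask])
                separation = separation or sep_j
            else:
                separation = True
            rows.append(
                {
                    "participant_id": pid,
                    "intercept_logit": params[0],
                    "coef_f0_logit": params[1],
                    "coef_vtl_logit": params[2],
                }
            )
        per = pd.DataFrame(rows)
        pop = per[["intercept_logit", "coef_f0_logit", "coef_vtl_logit"]].mean().to_numpy()
        used = "two_stage"
    else:
        raise ValueError("method must be 'mixed', 'pooled' or 'two_stage'")

    per["weight_f0_bk_per_st"] = per["coef_f0_logit"].map(lambda c: to_berkson_per_st(c, "F0"))
    per["weight_vtl_bk_per_st"] = per["coef_vtl_logit"].map(lambda c: to_berkson_per_st(c, "VTL"))
    return CueWeightFit(
        intercept_logit=float(pop[0]),
        coef_f0_logit=float(pop[1]),
        coef_vtl_logit=float(pop[2]),
        weight_f0_bk_per_st=to_berkson_per_st(float(pop[1]), "F0"),
        weight_vtl_bk_per_st=to_berkson_per_st(float(pop[2]), "VTL"),
        per_participant=per,
        method=used,
        separation_flag=separation,
        n_trials=int(y.size),
        n_participants=n_p,
    )
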