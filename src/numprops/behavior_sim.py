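"""Weber-law simulation of two-choice numerosity-comparison behavior.

The approximate-number-system (ANS) account holds that two numerosities n1
and n2 are encoded as noisy magnitudes with standard deviation proportional
to their size (scalar variability, Weber fraction ``w``).  Under the linear
ANS model the probability of a correct "which has more?" judgement is

    p(correct) = 1 - 1/2 * erfc( |n1 - n2| / (sqrt(2) * w * sqrt(n1² + n2²)) )

which approaches chance (0.5) as the two counts converge and 1 as either the
count difference grows or ``w`` shrinks.  This module simulates trial tables
in the standard schema (STIMID, USERID, RT, ERR, USERAGE, GENDER; ERR coded
1 = error, 0 = correct; age in months; gender 1 = male, 2 = female) and fits
``w`` back from aggregated accuracies by maximum likelihood
(:class:`WeberModel`).  It exists so the preprocessing and validation stages
are fully testable without any participant data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import erfc

__all__ = [
    "ParticipantModel",
    "TRIAL_COLUMNS",
    "p_correct",
    "sample_participants",
    "simulate_trials",
    "inject_outliers",
    "WeberModel",
    "WeberResults",
    "fit_weber",
]

TRIAL_COLUMNS = ["STIMID", "USERID", "RT", "ERR", "USERAGE", "GENDER"]

RT_FLOOR_MS = 150.0   # anticipatory-response floor
RT_CEIL_MS = 5000.0   # response window


@dataclass(frozen=True)
class ParticipantModel:
    """Latent parameters of one simulated participant."""

    user_id: int
    weber_w: float
    rt_base: float = 500.0        # ms
    rt_ratio_slope: float = 300.0  # ms per unit dot ratio (harder = slower)
    rt_sigma: float = 0.25         # log-scale SD of the RT noise
    age_months: int = 216
    gender: int = 1

    def __post_init__(self):
        if self.weber_w <= 0:
            raise ValueError("weber_w must be positive")
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if self.gender not in (1, 2):
            raise ValueError("gender must be 1 (male) or 2 (female)")


def p_correct(n1, n2, w) -> np.ndarray | float:
    """Probability of a correct comparison under the linear ANS model.

    Vectorized over ``n1``/``n2``.  Strictly increasing in |n1 - n2| at
    fixed n1² + n2²; exactly 0.5 when n1 == n2.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("Weber fraction w must be positive")
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("counts must be >= 1")
    z = np.abs(n1 - n2) / (np.sqrt(2.0) * w * np.hypot(n1, n2))
    out = 1.0 - 0.5 * erfc(z)
    return float(out) if out.ndim == 0 else out


def sample_participants(n: int, rng: np.random.Generator,
                        weber_median: float = 0.25,
                        weber_log_sd: float = 0.35,
                        age_range_months: tuple[int, int] = (72, 720)
                        ) -> list[ParticipantModel]:
    """Draw a heterogeneous participant pool.

    Weber fractions are log-normal around ``weber_median`` (individual
    differences in acuity span roughly a factor of two at the default SD).
    """
    ws = weber_median * np.exp(rng.normal(0.0, weber_log_sd, size=n))
    bases = rng.uniform(400.0, 700.0, size=n)
    slopes = rng.uniform(150.0, 450.0, size=n)
    ages = rng.integers(age_range_months[0], age_range_months[1] + 1, size=n)
    genders = rng.integers(1, 3, size=n)
    return [ParticipantModel(user_id=i + 1, weber_w=float(ws[i]),
                             rt_base=float(bases[i]),
                             rt_ratio_slope=float(slopes[i]),
                             age_months=int(ages[i]), gender=int(genders[i]))
            for i in range(n)]


def simulate_trials(stimlist: pd.DataFrame,
                    participants: list[ParticipantModel],
                    rng: np.random.Generator) -> pd.DataFrame:
    """One trial per participant x stimulus.

    Accuracy is Bernoulli with p from :func:`p_correct` at the participant's
    Weber fraction; RT = rt_base + rt_ratio_slope * (n_small/n_large) plus
    additive log-normal noise, truncated to [150, 5000] ms.  ``stimlist``
    needs columns STIMID, n_a, n_b.
    """
    if len(stimlist) == 0 or len(participants) == 0:
        raise ValueError("stimlist and participants must be non-empty")
    n_a = stimlist["n_a"].to_numpy(dtype=float)
    n_b = stimlist["n_b"].to_numpy(dtype=float)
    ratio = np.minimum(n_a, n_b) / np.maximum(n_a, n_b)
    stim_ids = stimlist["STIMID"].to_numpy()
    m = len(stimlist)
    frames = []
    for p in participants:
        pc = p_correct(n_a, n_b, p.weber_w)
        err = (rng.random(m) >= pc).astype(int)
        noise = np.exp(rng.normal(np.log(60.0), p.rt_sigma, size=m))
        rt = np.clip(p.rt_base + p.rt_ratio_slope * ratio + noise,
                     RT_FLOOR_MS, RT_CEIL_MS)
        frames.append(pd.DataFrame({
            "STIMID": stim_ids,
            "USERID": p.user_id,
            "RT": np.round(rt, 1),
            "ERR": err,
            "USERAGE": p.age_months,
            "GENDER": p.gender,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def inject_outliers(trials: pd.DataFrame, fraction: float,
                    slowdown_factor: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Slow down a random fraction of participants (exercises outlier exclusion).

    All RTs of the selected participants are multiplied by
    ``slowdown_factor`` and re-truncated at the 5000 ms response window.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    out = trials.copy()
    if fraction == 0:
        return out
    users = np.unique(out["USERID"].to_numpy())
    n_pick = int(round(fraction * len(users)))
    picked = rng.choice(users, size=n_pick, replace=False)
    mask = out["USERID"].isin(picked)
    out.loc[mask, "RT"] = np.minimum(out.loc[mask, "RT"] * slowdown_factor,
                                     RT_CEIL_MS)
    return out


# ---------------------------------------------------------------------------
# Weber-fraction recovery

class WeberResults:
    """MLE fit of the Weber fraction from aggregated accuracies."""

    def __init__(self, w: float, se: float, llf: float, nobs: int,
                 n_trials: int, at_bound: bool, bounds: tuple[float, float]):
        self.weber_w = w
        self.bse = se
        self.llf = llf
        self.nobs = nobs
        self.n_trials = n_trials
        self.at_bound = at_bound
        self.bounds = bounds

    def summary(self) -> str:
        lines = [
            "Weber fraction fit (binomial MLE, linear ANS model)",
            f"  w-hat        {self.weber_w:10.4f}",
            f"  std err      {self.bse:10.4f}",
            f"  log-lik      {self.llf:10.2f}",
            f"  stimuli      {self.nobs:10d}",
            f"  trials       {self.n_trials:10d}",
        ]
        if self.at_bound:
            lines.append("  WARNING: estimate at optimization bound")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<WeberResults w={self.weber_w:.4f} "
                f"se={self.bse:.4f} nobs={self.nobs}>")


class WeberModel:
    """Binomial likelihood for per-stimulus accuracy under the ANS model.

    Parameters
    ----------
    data : DataFrame with columns n1, n2, accuracy, n_trials
        One row per stimulus; ``accuracy`` is the observed proportion
        correct over ``n_trials`` trials.
    """

    def __init__(self, data: pd.DataFrame,
                 bounds: tuple[float, float] = (1e-3, 5.0)):
        req = {"n1", "n2", "accuracy", "n_trials"}
        missing = req - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        d = data.loc[data["n1"] != data["n2"]]
        ratios = np.unique(np.minimum(d.n1, d.n2) / np.maximum(d.n1, d.n2))
        if len(ratios) < 3:
            raise ValueError("need >= 3 distinct dot ratios to identify w")
        self.data = d.reset_index(drop=True)
        self.bounds = bounds

    def loglike(self, w: float) -> float:
        d = self.data
        p = np.clip(p_correct(d.n1.to_numpy(), d.n2.to_numpy(), w),
                    1e-12, 1 - 1e-12)
        k = d.accuracy.to_numpy() * d.n_trials.to_numpy()
        return float(np.sum(k * np.log(p)
                            + (d.n_trials.to_numpy() - k) * np.log1p(-p)))

    def fit(self) -> WeberResults:
        res = minimize_scalar(lambda w: -self.loglike(w), bounds=self.bounds,
                              method="bounded",
                              options={"xatol": 1e-6})
        w = float(res.x)
        lo, hi = self.bounds
        at_bound = w <= lo * 1.01 or w >= hi * 0.99
        if at_bound:
            warnings.warn("Weber estimate at optimization bound; data are "
                          "uninformative (all-chance or all-perfect)",
                          RuntimeWarning, stacklevel=2)
        # observed-information standard error via central differences
        h = max(1e-5, 1e-4 * w)
        d2 = (self.loglike(w + h) - 2 * self.loglike(w)
              + self.loglike(w - h)) / h**2
        se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.inf
        return WeberResults(w, se, float(-res.fun), len(self.data),
                            int(self.data.n_trials.sum()), at_bound,
                            self.bounds)


def fit_weber(per_stimulus_accuracy: pd.DataFrame,
              bounds: tuple[float, float] = (1e-3, 5.0)) -> WeberResults:
    """Convenience wrapper: fit the Weber fraction from aggregated accuracy."""
    return WeberModel(per_stimulus_accuracy, bounds=bounds).fit()
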