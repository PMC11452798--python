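"""Grid-search estimation of indirect-influence strengths from adopter curves.

For one session-setting, the observed per-round adopter proportions u_exp
are matched against model predictions u_pred obtained from the diffusion
u(t) = exp(−t(L₁ + c_d L_d)) u₀ — one free coefficient c_d per setting
(the distance the setting displays) — read off at r equispaced times in
[0, T] and thresholded at Δ.  The triplet (c_d, Δ, T) minimizing the mean
squared error over an exhaustive grid is the fit; the Pearson correlation
at the optimum is reported alongside.

Default grids: c in [0, 1] step 0.01, T in 10..1000 step 10,
Δ in {0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99} — 101 × 100 × 7 combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.stats import pearsonr

from .diffusion import AdoptionCurve, DiffusionParams, adopter_curve, build_generator, discretize_rounds, evolve
from .network import PathLaplacianSet

log = logging.getLogger(__name__)

__all__ = ["FitGrid", "FitResult", "predict_curve", "predict_curve_multi", "grid_search"]


@dataclass(frozen=True)
class FitGrid:
    """The exhaustive parameter grid searched per session-setting."""

    c_values: np.ndarray = field(default_factory=lambda: np.round(np.arange(0, 101) * 0.01, 2))
    T_values: np.ndarray = field(default_factory=lambda: np.arange(10, 1001, 10, dtype=float))
    delta_values: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99])
    )

    def __post_init__(self) -> None:
        for name in ("c_values", "T_values", "delta_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)

    @property
    def size(self) -> int:
        return len(self.c_values) * len(self.T_values) * len(self.delta_values)


@dataclass(frozen=True)
class FitResult:
    """Best-fitting (c_d, Δ, T) for one session-setting."""

    session_id: str
    setting: str
    d: int | None        # displayed distance; None for setting I
    c: float | None      # fitted coefficient; None for setting I
    delta: float
    T: float
    mse: float
    pearson: float       # NaN when the observed curve is constant
    curve: AdoptionCurve = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if np.isfinite(self.pearson) and not -1 - 1e-9 <= self.pearson <= 1 + 1e-9:
            raise ValueError("pearson out of [-1, 1]")


def predict_curve(
    laps: PathLaplacianSet,
    setting_d: int | None,
    c: float | None,
    delta: float,
    T: float,
    r: int,
    u0: np.ndarray,
    *,
    normalized: bool = True,
) -> AdoptionCurve:
    """Model adopter curve for one (c, Δ, T) triplet.

    ``setting_d=None`` (setting I) uses the direct-only generator L₁, in
    which case ``c`` is ignored.
    """
    coeff = {} if setting_d is None or c is None or c == 0.0 else {setting_d: float(c)}
    gen = build_generator(laps, DiffusionParams(coefficients=coeff))
    states = evolve(gen, u0, discretize_rounds(T, r))
    return adopter_curve(states, u0, delta, normalized=normalized)


def predict_curve_multi(
    laps: PathLaplacianSet,
    coefficients: dict[int, float],
    delta: float,
    T: float,
    r: int,
    u0: np.ndarray,
    *,
    normalized: bool = True,
) -> AdoptionCurve:
    """Model curve under the full multi-term generator L₁ + Σ c_d L_d —
    the optional several-coefficients-at-once mode (the per-setting fits
    use one free coefficient)."""
    gen = build_generator(laps, DiffusionParams(coefficients=dict(coefficients)))
    states = evolve(gen, u0, discretize_rounds(T, r))
    return adopter_curve(states, u0, delta, normalized=normalized)


def _pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan")
    return float(pearsonr(pred, obs).statistic)


def grid_search(
    observed: AdoptionCurve,
    laps: PathLaplacianSet,
    setting_d: int | None,
    u0: np.ndarray,
    *,
    grid: FitGrid | None = None,
    normalized: bool = True,
    session_id: str = "S1",
    setting: str = "?",
) -> FitResult:
    """Exhaustive MSE minimization over the (c, T, Δ) grid.

    Ties on MSE are broken toward the smallest (c, T, Δ) lexicographically
    (the most parsimonious model); ties are logged.  For setting I
    (``setting_d=None``) only (T, Δ) are searched.

    The search shares one symmetric eigendecomposition per coefficient
    value across the whole T × Δ subgrid, so the full 101 × 100 × 7 sweep
    on a 31-node network takes well under a second.
    """
    grid = grid if grid is not None else FitGrid()
    obs = np.asarray(observed.proportion, dtype=float)
    r = len(obs)
    if r < 3:
        raise ValueError(f"observed curve too short (r={r} < 3)")
    u0 = np.asarray(u0, dtype=float)
    n = u0.shape[0]
    cutoffs = grid.delta_values * (u0.mean() if normalized else 1.0)

    # all rounds of all T values in one flat time vector
    tgrid = np.stack([discretize_rounds(T, r) for T in grid.T_values])  # (nT, r)
    flat_t = tgrid.ravel()
    c_values = [None] if setting_d is None else list(grid.c_values)

    best = None  # (mse, ci, Ti, di)
    for ci, c in enumerate(c_values):
        coeff = {} if c is None or c == 0.0 else {setting_d: float(c)}
        gen = build_generator(laps, DiffusionParams(coefficients=coeff))
        lam, vec = eigh(gen)
        w = vec.T @ u0
        states = (np.exp(-np.outer(flat_t, lam)) * w) @ vec.T      # (nT*r, n)
        states = states.reshape(len(grid.T_values), r, n)
        running = np.maximum.accumulate(states, axis=1)            # (nT, r, n)
        counts = (running[..., None] > cutoffs).sum(axis=2)        # (nT, r, nΔ)
        mse = ((counts / n - obs[None, :, None]) ** 2).mean(axis=1)  # (nT, nΔ)
        m = mse.min()
        if best is None or m < best[0]:
            ti, di = np.argwhere(mse == m)[0]  # argwhere rows sorted: smallest T, then Δ
            best = (float(m), ci, int(ti), int(di))
        elif m == best[0]:
            log.debug("MSE tie at c=%s (kept earlier, smaller c)", c)

    _, ci, ti, di = best
    c_fit = None if setting_d is None else float(grid.c_values[ci])
    T_fit = float(grid.T_values[ti])
    d_fit = float(grid.delta_values[di])
    curve = predict_curve(laps, setting_d, c_fit, d_fit, T_fit, r, u0, normalized=normalized)
    pred = curve.proportion
    return FitResult(
        session_id=session_id,
        setting=setting,
        d=setting_d,
        c=c_fit,
        delta=d_fit,
        T=T_fit,
        mse=float(((pred - obs) ** 2).mean()),
        pearson=_pearson(pred, obs),
        curve=curve,
    )


def fit_session_frame(df, laps: PathLaplacianSet, *, grid: FitGrid | None = None,
                      normalized: bool = True, pad: bool = True):
    """Fit every (session, setting) in a tidy round-record frame.

    Curves from settings that ended early (consensus before the cap) are
    padded at the consensus value to the setting's maximum observed length
    (``pad=False`` fits the truncated curve instead).  Returns a pandas
    DataFrame of fit results.
    """
    import pandas as pd

    from .sessions import curve_from_records

    setting_d = {"I": None, "II": 2, "III": 3, "IV": 4}
    rows = []
    for (sid, setting), sub in df.groupby(["session_id", "setting"], sort=True):
        curve = curve_from_records(sub)
        r_target = int(df[df["setting"] == setting].groupby("session_id")["round"].max().max())
        if pad and curve.r < r_target:
            curve = curve.padded(r_target)
        first = sub[sub["round"] == 1].set_index("node")["chosen_color"]
        init = first.loc[list(laps.nodes)].to_numpy(float)  # align with matrix order
        if init.min() == init.max():  # degenerate: no minority to diffuse
            continue
        fit = grid_search(
            curve, laps, setting_d[str(setting)], init,
            grid=grid, normalized=normalized, session_id=str(sid), setting=str(setting),
        )
        rows.append(
            {
                "session": fit.session_id, "setting": fit.setting, "d": fit.d,
                "c": fit.c, "delta": fit.delta, "T": fit.T,
                "mse": fit.mse, "pearson": fit.pearson,
            }
        )
    return pd.DataFrame(rows)
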