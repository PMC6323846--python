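"""1:1 Langmuir binding kinetics for biolayer-interferometry sensorgrams.

Association at analyte concentration C follows
``R(t) = Req (1 - exp(-(ka C + kd) t))`` with plateau
``Req = Rmax C / (C + KD)``; dissociation decays from the association
endpoint as ``R(t) = R(t_assoc) exp(-kd t)``. A global fit shares ka, kd
and Rmax across all concentrations (one immobilized ligand surface), and
``KD = kd / ka`` is reported in nM at three significant figures, matching
the convention of instrument software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._seq import substream


@dataclass
class KineticParams:
    ka: float  # association rate constant, 1/(M s)
    kd: float  # dissociation rate constant, 1/s
    rmax: float = 1.0  # maximal response, response units

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be > 0")
        if self.kd < 0:
            raise ValueError("kd must be >= 0")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant in molar."""
        return self.kd / self.ka

    def req(self, concentration: float) -> float:
        """Equilibrium plateau response at the given analyte concentration."""
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        denom = concentration + self.KD
        return 0.0 if denom == 0 else self.rmax * concentration / denom


def model_response(
    params: KineticParams,
    concentration: float,
    t: np.ndarray | float,
    phase: str = "association",
    r_assoc_end: float | None = None,
) -> np.ndarray | float:
    """Model response at time(s) ``t`` (measured from the phase start)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if phase == "association":
        req = params.req(concentration)
        kobs = params.ka * concentration + params.kd
        return req * -np.expm1(-kobs * t)
    if phase == "dissociation":
        if r_assoc_end is None:
            raise ValueError("dissociation needs the association endpoint response")
        return r_assoc_end * np.exp(-params.kd * t)
    raise ValueError(f"unknown phase {phase!r}")


@dataclass
class Sensorgram:
    """One BLI trace: association then dissociation at fixed concentration."""

    concentration: float  # molar
    times: np.ndarray  # seconds from the association start, strictly increasing
    responses: np.ndarray
    t_assoc: float = 120.0
    t_dissoc: float = 180.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.responses):
            raise ValueError("times and responses must align")


def model_trace(params: KineticParams, concentration: float, times: np.ndarray,
                t_assoc: float) -> np.ndarray:
    """Full association+dissociation trace on an absolute time grid."""
    times = np.asarray(times, dtype=float)
    assoc = times <= t_assoc
    out = np.empty_like(times)
    out[assoc] = model_response(params, concentration, times[assoc], "association")
    r_end = model_response(params, concentration, t_assoc, "association")
    out[~assoc] = model_response(
        params, concentration, times[~assoc] - t_assoc, "dissociation", r_assoc_end=float(r_end)
    )
    return out


def simulate_sensorgrams(
    params: KineticParams,
    concentrations: list[float],
    t_assoc: float = 120.0,
    t_dissoc: float = 180.0,
    rate_hz: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Noisy model traces at each concentration, sampled at ``rate_hz``."""
    rng = substream(seed, "sensorgrams")
    dt = 1.0 / rate_hz
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for c in concentrations:
        resp = model_trace(params, c, times, t_assoc)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=len(times))
        out.append(Sensorgram(c, times.copy(), resp, t_assoc, t_dissoc, noise_sd))
    return out


@dataclass
class FitResult:
    params: KineticParams
    rss: float
    req: dict[float, float] = field(default_factory=dict)
    converged: bool = True
    n_curves: int = 0

    @property
    def kd_nm(self) -> float:
        return kd_from_rates(self.params.ka, self.params.kd)


def _estimate_kd0(gram: Sensorgram) -> float:
    """Log-linear regression on the dissociation tail."""
    mask = (gram.times > gram.t_assoc) & (gram.responses > 0)
    t = gram.times[mask] - gram.t_assoc
    if len(t) < 5:
        return 1e-2
    slope = np.polyfit(t, np.log(gram.responses[mask]), 1)[0]
    return max(-float(slope), 1e-6)


def global_fit(
    sensorgrams: list[Sensorgram],
    share_rmax: bool = True,
    max_iter: int = 500,
) -> FitResult:
    """Least-squares global fit of (ka, kd, Rmax) across all curves.

    Requires at least two curves at distinct positive concentrations; a
    0-concentration trace, if supplied, is used as the baseline reference
    and subtracted from every other trace. Optimization runs in log
    space to keep rates positive, converging when the relative parameter
    step falls below 1e-9.
    """
    zero = [g for g in sensorgrams if g.concentration == 0]
    curves = [g for g in sensorgrams if g.concentration > 0]
    if len({g.concentration for g in curves}) < 2:
        raise ValueError("global fitting needs >=2 distinct positive concentrations")
    baseline = None
    if zero:
        baseline = zero[0]
    data = []
    for g in curves:
        resp = g.responses
        if baseline is not None and len(baseline.times) == len(g.times):
            resp = resp - baseline.responses
        data.append((g.concentration, g.times, resp, g.t_assoc))

    high = max(curves, key=lambda g: g.concentration)
    kd0 = _estimate_kd0(high)
    ka0 = 1e5
    rmax0 = 1.5 * max(float(np.max(r)) for _, _, r, _ in data)
    n_rmax = 1 if share_rmax else len(data)
    x0 = np.concatenate([[math.log(ka0), math.log(kd0)], np.full(n_rmax, math.log(rmax0))])

    def residuals(x):
        ka, kd = math.exp(x[0]), math.exp(x[1])
        res = []
        for i, (c, t, r, ta) in enumerate(data):
            rmax = math.exp(x[2] if share_rmax else x[2 + i])
            p = KineticParams(ka, kd, rmax)
            res.append(model_trace(p, c, t, ta) - r)
        return np.concatenate(res)

    sol = least_squares(residuals, x0, xtol=1e-9, ftol=1e-15, gtol=1e-15, max_nfev=max_iter * 10)
    ka, kd = math.exp(sol.x[0]), math.exp(sol.x[1])
    rmax = math.exp(sol.x[2]) if share_rmax else float(np.exp(sol.x[2:]).mean())
    params = KineticParams(ka, kd, rmax)
    req = {c: params.req(c) for c, _, _, _ in data}
    return FitResult(
        params=params,
        rss=float(np.sum(sol.fun**2)),
        req=req,
        converged=bool(sol.success),
        n_curves=len(data),
    )


def round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def kd_from_rates(ka: float, kd: float, sig: int = 3) -> float:
    """KD = kd/ka in nM, rounded to the reported precision (3 sig figs)."""
    if ka <= 0:
        raise ValueError("ka must be > 0")
    if kd < 0:
        raise ValueError("kd must be >= 0")
    return round_sig(kd / ka * 1e9, sig)


def write_sensorgrams_csv(sensorgrams: list[Sensorgram], path) -> None:
    with open(path, "w") as fh:
        fh.write("time,response,concentration,phase\n")
        for g in sensorgrams:
            for t, r in zip(g.times, g.responses):
                phase = "association" if t <= g.t_assoc else "dissociation"
                fh.write(f"{t:.3f},{r:.6g},{g.concentration:.6g},{phase}\n")


def read_sensorgrams_csv(path, t_assoc: float = 120.0, t_dissoc: float = 180.0) -> list[Sensorgram]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for c, grp in df.groupby("concentration"):
        grp = grp.sort_values("time")
        out.append(
            Sensorgram(
                float(c),
                grp["time"].to_numpy(float),
                grp["response"].to_numpy(float),
                t_assoc,
                t_dissoc,
            )
        )
    return out


def write_fit_tsv(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("ka_per_M_s\tkd_per_s\tKD_nM\trmax\trss\tconverged\n")
        fh.write(
            f"{fit.params.ka:.4g}\t{fit.params.kd:.4g}\t{fit.kd_nm:.4g}\t"
            f"{fit.params.rmax:.4g}\t{fit.rss:.4g}\t{int(fit.converged)}\n"
        )
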