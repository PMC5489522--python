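"""Model-evaluation statistics for paired observed/simulated series.

The four metrics conventionally reported for crop-model evaluation:
relative root mean square error (RRMSE, %, optimum 0), Nash-Sutcliffe
modelling efficiency (EF, optimum 1), coefficient of residual mass (CRM,
optimum 0; negative = overestimation) and the squared Pearson correlation
(R2).
"""

from __future__ import annotations

import numpy as np


def _paired(observed, simulated) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("observed and simulated must be 1-D arrays of equal length")
    if obs.size == 0:
        raise ValueError("series must be non-empty")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(sim))):
        raise ValueError("series must be finite")
    return obs, sim


def rrmse(observed, simulated) -> float:
    """Relative root mean square error (%): 100 * RMSE / mean(observed)."""
    obs, sim = _paired(observed, simulated)
    m = obs.mean()
    if m == 0.0:
        raise ValueError("rrmse undefined for zero observed mean")
    return float(100.0 * np.sqrt(np.mean((sim - obs) ** 2)) / m)


def modelling_efficiency(observed, simulated) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SStot; 1 is perfect, <0 worse than the mean."""
    obs, sim = _paired(observed, simulated)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("modelling efficiency undefined for zero observed variance")
    return float(1.0 - np.sum((sim - obs) ** 2) / ss_tot)


def crm(observed, simulated) -> float:
    """Coefficient of residual mass: (sum(obs) - sum(sim)) / sum(obs).

    Negative values flag systematic overestimation.
    """
    obs, sim = _paired(observed, simulated)
    s = float(obs.sum())
    if s == 0.0:
        raise ValueError("crm undefined for zero observed sum")
    return float((s - sim.sum()) / s)


def r_squared(observed, simulated) -> float:
    """Squared Pearson correlation between observed and simulated."""
    obs, sim = _paired(observed, simulated)
    if np.var(obs) == 0.0 or np.var(sim) == 0.0:
        raise ValueError("r_squared undefined for a zero-variance series")
    r = np.corrcoef(obs, sim)[0, 1]
    return float(r * r)


def evaluate_all(observed, simulated) -> dict[str, float]:
    """All four metrics as a dict (keys: rrmse, ef, crm, r2)."""
    return {
        "rrmse": rrmse(observed, simulated),
        "ef": modelling_efficiency(observed, simulated),
        "crm": crm(observed, simulated),
        "r2": r_squared(observed, simulated),
    }
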