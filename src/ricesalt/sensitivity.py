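"""Variance-based (Sobol') sensitivity analysis and ideotype extraction.

The ideotyping workflow perturbs the ten trait parameters around their
genotype means (normal marginals, sd = 5 % of the mean), runs the coupled
model for every sampled parameter vector, and decomposes the variance of
final yield into first-order and total-order Sobol' indices.  The sample
size follows the power-of-two rule ``M = 2**(q+3) * (2n + 2)`` with the
smallest ``q`` such that ``M`` strictly exceeds ``gamma * n`` runs.  The
ideotype is simply the sampled parameter vector achieving the highest
yield.

The Saltelli cross-sampling design (A, B, AB_i, BA_i blocks from a
scrambled Sobol' low-discrepancy sequence) and Jansen's estimators are
implemented here; both cross blocks are used, so each index is the
average of two half-sample estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .parameters import TraitParameters


@dataclass(frozen=True)
class ParameterDistributionSet:
    """Marginal distributions of the sensitivity-analysis parameters.

    Families are ``normal`` (mean/sd, truncated by clipping at +-4 sd and
    at the physical bounds) or ``uniform`` (bounds only, for benchmark
    functions).  The default set carries the ten trait parameters with
    sd = 5 % of the mean.
    """

    names: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    families: tuple[str, ...] = ()
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.means) == len(self.sds) == n):
            raise ValueError("names, means and sds must have equal length")
        if not self.families:
            object.__setattr__(self, "families", ("normal",) * n)
        if not self.lower:
            object.__setattr__(self, "lower", (-np.inf,) * n)
        if not self.upper:
            object.__setattr__(self, "upper", (np.inf,) * n)
        for f in self.families:
            if f not in ("normal", "uniform"):
                raise ValueError(f"unknown family {f!r}")

    @property
    def n_params(self) -> int:
        return len(self.names)

    @classmethod
    def for_traits(
        cls,
        means: TraitParameters | None = None,
        rel_sd: float = 0.05,
    ) -> "ParameterDistributionSet":
        """The trait parameter set: normal marginals, sd = ``rel_sd``·mean."""
        means = means or TraitParameters()
        vec = means.to_vector()
        names = TraitParameters.FIELD_ORDER
        # physical bounds: fractions to [0,1] (sub_dep_eff kept below 1 to
        # avoid the deposition singularity), everything else positive
        lower, upper = [], []
        for nm in names:
            if nm in ("sub_dep_eff", "na_to_pan", "part_cap"):
                lower.append(0.0)
                upper.append(0.999)
            elif nm == "rrbf_min":
                lower.append(1e-6)
                upper.append(100.0)
            else:
                lower.append(1e-9)
                upper.append(np.inf)
        return cls(
            names=tuple(names),
            means=tuple(vec),
            sds=tuple(rel_sd * v for v in vec),
            families=("normal",) * len(names),
            lower=tuple(lower),
            upper=tuple(upper),
        )


@dataclass(frozen=True)
class SobolResult:
    """First-/total-order indices with bootstrap CIs and output summaries."""

    names: tuple[str, ...]
    first_order: np.ndarray
    total_order: np.ndarray
    first_ci: np.ndarray          # (n, 2) percentile bounds
    total_ci: np.ndarray
    sample_size: int
    output_mean: float
    output_sd: float
    degenerate: bool = False      # zero output variance: indices undefined

    def ranking(self, order: str = "total") -> list[str]:
        """Parameter names sorted by decreasing index."""
        vals = self.total_order if order == "total" else self.first_order
        return [self.names[i] for i in np.argsort(vals)[::-1]]


def sobol_sample_size(n_params: int, gamma: float) -> int:
    """Smallest ``M = 2**(q+3) * (2n+2)`` strictly exceeding ``gamma * n``.

    ``gamma`` is the suggested number of model runs per parameter; the
    power-of-two base keeps the design compatible with Sobol' sequences.
    """
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    target = gamma * n_params
    q = 1
    while True:
        m = 2 ** (q + 3) * (2 * n_params + 2)
        if m > target:
            return m
        q += 1


def base_sample_size(n_params: int, gamma: float) -> int:
    """The per-block base sample ``2**(q+3)`` behind :func:`sobol_sample_size`."""
    return sobol_sample_size(n_params, gamma) // (2 * n_params + 2)


def _marginal_transform(u: np.ndarray, dists: ParameterDistributionSet) -> np.ndarray:
    """Map uniform(0,1) columns onto the configured marginals."""
    out = np.empty_like(u)
    eps = 1e-12
    for j in range(dists.n_params):
        col = np.clip(u[:, j], eps, 1.0 - eps)
        if dists.families[j] == "normal":
            x = stats.norm.ppf(col, loc=dists.means[j], scale=max(dists.sds[j], 0.0)) \
                if dists.sds[j] > 0 else np.full_like(col, dists.means[j])
            lo = max(dists.lower[j], dists.means[j] - 4.0 * dists.sds[j])
            hi = min(dists.upper[j], dists.means[j] + 4.0 * dists.sds[j])
            out[:, j] = np.clip(x, lo, hi)
        else:  # uniform over [lower, upper]
            lo, hi = dists.lower[j], dists.upper[j]
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("uniform marginals need finite bounds")
            out[:, j] = lo + col * (hi - lo)
    return out


def saltelli_sample(
    dists: ParameterDistributionSet, base_n: int, seed: int
) -> np.ndarray:
    """Saltelli cross-sampling design: ``base_n * (2n + 2)`` parameter rows.

    Blocks, in order: A, B, then AB_i (A with column i from B) and BA_i
    for each parameter i.  A and B come from a scrambled Sobol' sequence
    in 2n dimensions; ``base_n`` must be a power of two.
    """
    n = dists.n_params
    if base_n < 2 or (base_n & (base_n - 1)) != 0:
        raise ValueError("base_n must be a power of two >= 2")
    sampler = stats.qmc.Sobol(d=2 * n, scramble=True, seed=seed)
    u = sampler.random_base2(int(np.log2(base_n)))
    a = _marginal_transform(u[:, :n], dists)
    b = _marginal_transform(u[:, n:], dists)
    blocks = [a, b]
    for i in range(n):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    for i in range(n):
        ba = b.copy()
        ba[:, i] = a[:, i]
        blocks.append(ba)
    return np.vstack(blocks)


def _split_blocks(outputs: np.ndarray, n: int, base_n: int):
    fa = outputs[:base_n]
    fb = outputs[base_n : 2 * base_n]
    fab = [outputs[(2 + i) * base_n : (3 + i) * base_n] for i in range(n)]
    fba = [outputs[(2 + n + i) * base_n : (3 + n + i) * base_n] for i in range(n)]
    return fa, fb, fab, fba


def _jansen(fa, fb, fab_i, fba_i, idx=None):
    """Symmetrised Jansen estimators of (V_i, E_i) where S=V_i/V, ST=E_i/V."""
    if idx is not None:
        fa, fb = fa[idx], fb[idx]
        fab_i, fba_i = fab_i[idx], fba_i[idx]
    v = np.var(np.concatenate([fa, fb]))
    n = fa.size
    vi = 0.5 * (
        (v - 0.5 * np.mean((fb - fab_i) ** 2)) + (v - 0.5 * np.mean((fa - fba_i) ** 2))
    )
    ei = 0.5 * (0.5 * np.mean((fa - fab_i) ** 2) + 0.5 * np.mean((fb - fba_i) ** 2))
    return vi, ei, v


def sobol_indices(
    outputs: np.ndarray,
    design: np.ndarray,
    n_params: int | None = None,
    names: Sequence[str] | None = None,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SobolResult:
    """Estimate first-/total-order indices from a Saltelli-design output vector.

    ``outputs`` must align row-for-row with the design returned by
    :func:`saltelli_sample`.  Bootstrap CIs resample the base rows jointly
    across all blocks.
    """
    outputs = np.asarray(outputs, dtype=float)
    n = n_params if n_params is not None else design.shape[1]
    if outputs.size % (2 * n + 2) != 0:
        raise ValueError("output length is not a multiple of 2n+2 blocks")
    base_n = outputs.size // (2 * n + 2)
    if design is not None and design.shape[0] != outputs.size:
        raise ValueError("outputs are not aligned with the design rows")
    names = tuple(names) if names is not None else tuple(f"x{i+1}" for i in range(n))

    fa, fb, fab, fba = _split_blocks(outputs, n, base_n)
    v_total = np.var(np.concatenate([fa, fb]))
    mean_out = float(np.mean(np.concatenate([fa, fb])))
    sd_out = float(np.sqrt(v_total))
    if v_total <= 0.0:
        nan = np.full(n, np.nan)
        return SobolResult(
            names=names, first_order=nan, total_order=nan.copy(),
            first_ci=np.full((n, 2), np.nan), total_ci=np.full((n, 2), np.nan),
            sample_size=outputs.size, output_mean=mean_out, output_sd=0.0,
            degenerate=True,
        )

    first = np.empty(n)
    total = np.empty(n)
    for i in range(n):
        vi, ei, v = _jansen(fa, fb, fab[i], fba[i])
        first[i] = vi / v
        total[i] = ei / v

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    boots_f = np.empty((n_boot, n))
    boots_t = np.empty((n_boot, n))
    for b in range(n_boot):
        idx = rng.integers(0, base_n, base_n)
        for i in range(n):
            vi, ei, v = _jansen(fa, fb, fab[i], fba[i], idx=idx)
            if v <= 0:
                boots_f[b, i] = np.nan
                boots_t[b, i] = np.nan
            else:
                boots_f[b, i] = vi / v
                boots_t[b, i] = ei / v
    first_ci = np.nanpercentile(boots_f, [100 * alpha, 100 * (1 - alpha)], axis=0).T
    total_ci = np.nanpercentile(boots_t, [100 * alpha, 100 * (1 - alpha)], axis=0).T

    return SobolResult(
        names=names, first_order=first, total_order=total,
        first_ci=first_ci, total_ci=total_ci, sample_size=outputs.size,
        output_mean=mean_out, output_sd=sd_out,
    )


def select_ideotype(design: np.ndarray, outputs: np.ndarray) -> np.ndarray:
    """The sampled parameter vector achieving the highest output.

    Ties are broken by the lowest row index.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.size == 0:
        raise ValueError("outputs must be non-empty")
    return np.asarray(design)[int(np.argmax(outputs))]


def run_sensitivity(
    scenario,
    *,
    dists: ParameterDistributionSet | None = None,
    gamma: float = 500.0,
    base_n: int | None = None,
    season_length: int = 150,
    weather_seed: int = 0,
    sample_seed: int = 0,
    aux=None,
    host=None,
    n_boot: int = 100,
) -> tuple[SobolResult, np.ndarray, np.ndarray]:
    """Full trait-sensitivity workflow for one salinity scenario.

    Samples trait vectors, runs a season per vector against one synthetic
    weather year and the scenario's salinity series, and returns
    ``(SobolResult, design, outputs)``; the ideotype is
    ``select_ideotype(design, outputs)``.  ``base_n`` defaults to the
    power-of-two implied by the sample-size rule.
    """
    from .host_crop import run_season
    from .scenarios import make_weather, make_salinity_series
    from .parameters import AuxiliaryConstants, HostParameters

    dists = dists or ParameterDistributionSet.for_traits()
    aux = aux or AuxiliaryConstants()
    host = host or HostParameters()
    n = dists.n_params
    if base_n is None:
        base_n = base_sample_size(n, gamma)
    design = saltelli_sample(dists, base_n, sample_seed)
    weather = make_weather(season_length, weather_seed)
    salinity = make_salinity_series(scenario, season_length)
    outputs = np.empty(design.shape[0])
    for r in range(design.shape[0]):
        params = TraitParameters.from_vector(design[r])
        res = run_season(
            weather, params, aux, host, salinity=salinity, record=False
        )
        outputs[r] = res.final_yield
    result = sobol_indices(
        outputs, design, n_params=n, names=dists.names, n_boot=n_boot, seed=sample_seed
    )
    return result, design, outputs
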