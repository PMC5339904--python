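"""Synthetic-data generator for the selection screen and LD50 workflow.

Two forward models live here:

* noisy decreasing-sigmoid dose-response plates for the LD50 fitting stage;
* a stochastic two-step ampicillin selection (agar plate, then liquid
  culture) over the combinatorial pair library, with per-cell Bernoulli
  survival governed by a Hill-type survival curve.

The ground-truth affinity model encodes, as explicit multiplicative
factors, the qualitative drivers of pair affinity that the analysis stages
are meant to recover: opposite charges help most, the 6/7 position pair is
best, close spacing helps, like charges are weak.  It is a test harness,
not an inference.

All randomness flows through explicitly passed ``numpy.random.Generator``
instances; identical config and seed give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from tmdscreen.dose_response import DoseResponseSeries, HillParams, hill
from tmdscreen.library_design import TMDPair, enumerate_pairs
from tmdscreen.pattern_stats import classify_charge_pair, residue_spacing

__all__ = [
    "AffinityModel",
    "ScreenConfig",
    "survival_probability",
    "assign_true_ld50",
    "simulate_dose_response",
    "simulate_selection",
    "simulate_control_discrimination",
]


@dataclass(frozen=True)
class AffinityModel:
    """Ground-truth LD50 generator for library pairs.

    The uncharged (backbone/backbone) pair has mean LD50 ``base_ld50``;
    the synthetic reference homodimer, against which relative affinities
    are expressed, has ``reference_ld50``.  The default calibration puts
    the uncharged pair at 37% of the reference.
    """

    base_ld50: float = 37.0
    reference_ld50: float = 100.0
    bonus_opposite: float = 3.0
    bonus_positions_67: float = 1.4
    penalty_like: float = 0.8
    bonus_single: float = 1.0
    spacing_decay: float = 0.85
    noise_cv: float = 0.15

    def __post_init__(self):
        factors = (
            self.bonus_opposite,
            self.bonus_positions_67,
            self.penalty_like,
            self.bonus_single,
            self.spacing_decay,
        )
        if any(f <= 0 for f in factors):
            raise ValueError("all affinity factors must be positive")
        if not 0 < self.base_ld50 < self.reference_ld50:
            raise ValueError("require 0 < base_ld50 < reference_ld50")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def mean_ld50(self, pair: TMDPair) -> float:
        """Deterministic mean LD50 from charge class, positions, spacing."""
        relation = classify_charge_pair(pair).value
        ld50 = self.base_ld50
        if relation == "opposite":
            ld50 *= self.bonus_opposite
        elif relation == "like":
            ld50 *= self.penalty_like
        elif relation == "single":
            ld50 *= self.bonus_single
        spacing = residue_spacing(pair)
        if spacing is not None:
            ld50 *= self.spacing_decay ** max(0, spacing - 1)
            positions = {pair.n_variant.position, pair.c_variant.position}
            if positions == {6, 7}:
                ld50 *= self.bonus_positions_67
        return ld50


@dataclass(frozen=True)
class ScreenConfig:
    """Two-step selection settings; the seed is always explicit."""

    seed: int
    plate_amp: float = 5.0
    liquid_amp: float = 30.0
    transformant_excess: float = 10.0
    cells_plated: Optional[int] = None  # default: excess x library size
    survival_g: float = 4.0

    def __post_init__(self):
        if self.plate_amp < 0 or self.liquid_amp < 0:
            raise ValueError("ampicillin concentrations must be >= 0")
        if self.cells_plated is not None and self.cells_plated <= 0:
            raise ValueError("cells_plated must be positive")
        if self.survival_g <= 0:
            raise ValueError("survival_g must be positive")

    def n_cells(self, library_size: int) -> int:
        if self.cells_plated is not None:
            return self.cells_plated
        return int(round(self.transformant_excess * library_size))


def survival_probability(dose: float, ld50: float, g: float) -> float:
    """Per-cell survival ``1 / (1 + (dose/ld50)**g)``; S(0) = 1."""
    if ld50 <= 0:
        raise ValueError("ld50 must be positive")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0.0:
        return 1.0
    if math.isinf(ld50):
        return 1.0
    try:
        ratio = (dose / ld50) ** g
    except OverflowError:
        return 0.0
    return 1.0 / (1.0 + ratio)


def assign_true_ld50(
    pair: TMDPair, model: AffinityModel, rng: np.random.Generator
) -> float:
    """Mean LD50 for the pair times a log-normal clone factor with
    coefficient of variation ``model.noise_cv``."""
    mean = model.mean_ld50(pair)
    if model.noise_cv == 0:
        return mean
    # log-normal with E[factor] = 1 and CV = noise_cv
    sigma2 = math.log(1.0 + model.noise_cv**2)
    factor = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2))
    return mean * factor


def simulate_dose_response(
    true: HillParams,
    concentrations: Sequence[float],
    noise_sd: float,
    replicates: int,
    rng: np.random.Generator,
    pair_id: str = "sim",
    condition: str = "",
) -> list[DoseResponseSeries]:
    """Hill curve plus i.i.d. Gaussian noise, truncated at 0, per replicate."""
    conc = np.asarray(list(concentrations), dtype=float)
    if 0.0 not in conc:
        raise ValueError("concentrations must include 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    clean = hill(conc, true.c, true.k, true.g)
    series = []
    for r in range(replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, 0.0, None)
        series.append(
            DoseResponseSeries(
                pair_id=pair_id,
                replicate_id=f"rep{r + 1}",
                concentrations=tuple(conc),
                responses=tuple(noisy),
                condition=condition,
            )
        )
    return series


def _two_step_survival(ld50: float, config: ScreenConfig) -> float:
    return survival_probability(
        config.plate_amp, ld50, config.survival_g
    ) * survival_probability(config.liquid_amp, ld50, config.survival_g)


def simulate_selection(
    library: Sequence[TMDPair],
    model: AffinityModel,
    config: ScreenConfig,
    rng: Optional[np.random.Generator] = None,
    frequencies: Optional[Sequence[float]] = None,
) -> list[TMDPair]:
    """Two-step plate/liquid selection over the library.

    Each plated cell draws a pair (uniformly, or per ``frequencies``) and a
    clone LD50; it survives the agar plate with probability S(plate_amp)
    and, if picked, passes the liquid step with probability S(liquid_amp).
    Returns the distinct pairs among passing colonies with their
    multiplicities in ``observed_count`` and the clone's relative affinity
    attached; an empty list is a valid outcome.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_cells = config.n_cells(len(library))
    if frequencies is not None:
        freq = np.asarray(frequencies, dtype=float)
        if freq.shape != (len(library),) or np.any(freq < 0) or freq.sum() == 0:
            raise ValueError("frequencies must be non-negative, one per pair")
        freq = freq / freq.sum()
    else:
        freq = None
    draws = rng.choice(len(library), size=n_cells, p=freq)

    from tmdscreen.dose_response import classify_affinity

    mean_ld50 = np.array([model.mean_ld50(p) for p in library])
    ld50 = mean_ld50[draws]
    if model.noise_cv > 0:
        sigma2 = math.log(1.0 + model.noise_cv**2)
        ld50 = ld50 * rng.lognormal(
            mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n_cells
        )

    def _survive(dose: float) -> np.ndarray:
        if dose == 0.0:
            s = np.ones(n_cells)
        else:
            s = 1.0 / (1.0 + (dose / ld50) ** config.survival_g)
        return rng.random(n_cells) < s

    passed = _survive(config.plate_amp) & _survive(config.liquid_amp)

    isolates = []
    for idx in np.unique(draws[passed]):
        clone_ld50s = ld50[passed & (draws == idx)]
        percent = 100.0 * float(clone_ld50s.mean()) / model.reference_ld50
        isolates.append(
            replace(
                library[int(idx)],
                observed_count=int(clone_ld50s.size),
                percent_of_reference=percent,
                affinity_class=classify_affinity(percent),
            )
        )
    return isolates


def simulate_control_discrimination(
    wt_ld50: float,
    mut_ld50: float,
    config: ScreenConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Expected wild-type:mutant survivor ratios for the plate step alone
    and for the full two-step selection, used to calibrate ``survival_g``.

    Analytic (deterministic) ratios of expected survivor counts for two
    single-pair libraries plated at equal depth; an ``rng`` may be passed
    for interface symmetry but is unused.  A mutant with zero expected
    survivors yields ``math.inf``.
    """
    if wt_ld50 <= 0 or mut_ld50 <= 0:
        raise ValueError("LD50 values must be positive")
    s_wt_plate = survival_probability(config.plate_amp, wt_ld50, config.survival_g)
    s_mut_plate = survival_probability(config.plate_amp, mut_ld50, config.survival_g)
    if s_mut_plate == 0.0:
        return math.inf, math.inf
    plate_ratio = s_wt_plate / s_mut_plate
    s_wt_two = _two_step_survival(wt_ld50, config)
    s_mut_two = _two_step_survival(mut_ld50, config)
    two_step_ratio = math.inf if s_mut_two == 0.0 else s_wt_two / s_mut_two
    return plate_ratio, two_step_ratio


def default_screen(seed: int) -> tuple[list[TMDPair], AffinityModel, ScreenConfig]:
    """Convenience: the full 1089-pair library with default model/config."""
    return enumerate_pairs(), AffinityModel(), ScreenConfig(seed=seed)


def calibrate_survival(
    ld50_ratio: float = 100.0 / 29.0,
    target_plate: float = 5.0,
    target_two_step: float = 30.0,
    plate_amp: float = 5.0,
    liquid_amp: float = 30.0,
    g_grid: Optional[Sequence[float]] = None,
) -> tuple[float, float, float, float]:
    """Scan the survival steepness for a setting that reproduces the
    plate-step and two-step wild-type:mutant discrimination targets.

    For each candidate ``g`` the wild-type LD50 scale is solved (bisection)
    so the plate-step survivor ratio hits ``target_plate``; the candidate
    whose resulting two-step ratio is closest to ``target_two_step`` wins.
    Returns ``(survival_g, wt_ld50, plate_ratio, two_step_ratio)``.  The
    maximum attainable ratio at steepness g is ``ld50_ratio ** g``, so
    candidates below ``log(target_plate)/log(ld50_ratio)`` are skipped.
    """
    from scipy.optimize import brentq

    if g_grid is None:
        g_grid = np.arange(0.5, 8.01, 0.05)
    best = None
    for g in g_grid:
        if ld50_ratio**g <= target_plate * 1.001:
            continue
        config = ScreenConfig(
            seed=0, plate_amp=plate_amp, liquid_amp=liquid_amp, survival_g=g
        )

        def plate_gap(wt, _g=g, _config=config):
            ratio, _ = simulate_control_discrimination(
                wt, wt / ld50_ratio, _config
            )
            return ratio - target_plate

        # plate ratio decreases in the wt LD50 scale: bracket and bisect
        lo, hi = 1e-3, 1e4
        if plate_gap(lo) < 0 or plate_gap(hi) > 0:
            continue
        wt = brentq(plate_gap, lo, hi, xtol=1e-9)
        plate_ratio, two_step_ratio = simulate_control_discrimination(
            wt, wt / ld50_ratio, config
        )
        gap = abs(two_step_ratio - target_two_step)
        if best is None or gap < best[0]:
            best = (gap, float(g), float(wt), plate_ratio, two_step_ratio)
    if best is None:
        raise RuntimeError("no steepness in the grid can reach the targets")
    _, g, wt, plate_ratio, two_step_ratio = best
    return g, wt, plate_ratio, two_step_ratio
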