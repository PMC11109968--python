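"""Fitting energy matrices to probe binding data.

The estimator maximizes the Pearson correlation r between predicted probe
occupancies and measured binding signals over the L x 4 energy matrix (and,
optionally, the unspecific energy dG0 with a penalty holding the maximal
per-probe occupancy near a physical target).  Optimization is unconstrained
smooth quasi-Newton (L-BFGS) with an analytic gradient; the zero-sum gauge is
projected on return, which is harmless because the objective is
gauge-invariant.

The public surface follows the Model/Results convention: ``BindingModel`` is
built from a :class:`~pbmotif.probeio.ProbeSet`, its ``fit`` /
``fit_multistart`` return :class:`FitResult` objects carrying the fitted
matrix, the correlation, the mean absolute error after a free linear mapping
of occupancy to signal, and convergence metadata.  Module-level functions
(`fit`, `predict`, `score`, `calibrate_dG0`, `multi_start_fit`) are thin
wrappers for script use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .probeio import ProbeSet
from .thermo import (EnergyMatrix, WindowDesign, normalize_matrix,
                     random_start_matrix)

logger = logging.getLogger(__name__)

_MAX_SEED = 2 ** 31


class DegenerateObjectiveError(ValueError):
    """Signals (or occupancies) without variance: Pearson r is undefined."""


@dataclass
class FitConfig:
    """Settings for a single energy-matrix fit.

    Attributes
    ----------
    motif_length : int
        L, the number of positions of the energy matrix.
    strandedness : str or None
        "single" or "double"; None takes the ProbeSet's own value.
    start_matrix : EnergyMatrix or "random"
        Starting point; random starts draw i.i.d. N(0, init_sd^2) entries,
        gauge-projected, with dG0 set by calibrating the start matrix to
        ``occupancy_target``.
    fit_dG0 : bool
        Include dG0 explicitly in the parameter vector and add the
        max-occupancy penalty ``penalty_weight * (max_occ - occupancy_target)^2``
        to the objective.
    ds_rule : str
        Combination of forward/reverse occupancies at one offset for
        double-stranded probes: "clip" (sum, capped at 1) or "competitive".
    """

    motif_length: int = 3
    strandedness: str | None = None
    start_matrix: EnergyMatrix | str = "random"
    seed: int = 0
    fit_dG0: bool = False
    occupancy_target: float = 1.0
    penalty_weight: float = 10.0
    max_iter: int = 500
    tol: float = 1e-6
    init_sd: float = 0.5
    ds_rule: str = "clip"

    def __post_init__(self):
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.penalty_weight <= 0:
            raise ValueError("penalty_weight must be positive")


@dataclass
class FitResult:
    """Outcome of one energy-matrix fit (the Results object of the model)."""

    matrix: EnergyMatrix
    pearson_r: float
    mae: float
    occupancies: np.ndarray
    max_occupancy: float
    converged: bool
    n_iter: int
    seed: int
    objective: float = np.nan
    config: FitConfig | None = None

    def summary(self) -> str:
        """Human-readable report of the fitted motif model."""
        from .logo import energy_to_frequency, information_content

        m = self.matrix
        freq = energy_to_frequency(m)
        per_pos, total = information_content(freq)
        lines = [
            "Thermodynamic binding motif fit",
            "=" * 46,
            f"motif length:      {m.length}",
            f"probes:            {self.occupancies.size}",
            f"Pearson r:         {self.pearson_r:.4f}",
            f"mae (lin. map):    {self.mae:.4f}",
            f"dG0 (RT):          {m.dG0:.4f}",
            f"max occupancy:     {self.max_occupancy:.4f}",
            f"information (bit): {total:.2f}",
            f"converged:         {self.converged} ({self.n_iter} iterations)",
            "",
            "ddG matrix (RT units; negative favours binding)",
            "pos" + "".join(f"{b:>9}" for b in "ACGT") + "     bits",
        ]
        for p in range(m.length):
            row = "".join(f"{x:9.3f}" for x in m.ddG[p])
            lines.append(f"{p:3d}{row} {per_pos[p]:8.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# objective


def _pearson_and_grad(occ: np.ndarray, y_centered: np.ndarray, Svv: float):
    """Pearson r between occ and the (pre-centered) signals, and dr/d occ."""
    u = occ - occ.mean()
    Suu = float(u @ u)
    if Suu < 1e-300 or Svv < 1e-300:
        return 0.0, np.zeros_like(occ)
    Suv = float(u @ y_centered)
    denom = np.sqrt(Suu * Svv)
    r = Suv / denom
    grad = (y_centered - (Suv / Suu) * u) / denom
    return r, grad


def _objective(theta, design: WindowDesign, y_centered, Svv, base_matrix,
               free_pos, cfg: FitConfig):
    """Negative penalized objective and its gradient w.r.t. theta.

    theta = [free ddG columns flattened] (+ [dG0] when cfg.fit_dG0).
    """
    L = design.L
    ddG = base_matrix.ddG.copy()
    n_free = len(free_pos)
    ddG[free_pos] = theta[:4 * n_free].reshape(n_free, 4)
    dG0 = theta[-1] if cfg.fit_dG0 else base_matrix.dG0
    m = EnergyMatrix.__new__(EnergyMatrix)  # skip validation in the hot loop
    object.__setattr__(m, "ddG", ddG)
    object.__setattr__(m, "dG0", float(dG0))
    object.__setattr__(m, "protein_conc", base_matrix.protein_conc)

    occ, terms = design.occupancies_and_terms(m, cfg.ds_rule)
    r, dr_docc = _pearson_and_grad(occ, y_centered, Svv)
    obj = r
    dJ_docc = dr_docc
    if cfg.fit_dG0:
        i_max = int(np.argmax(occ))
        dev = occ[i_max] - cfg.occupancy_target
        obj -= cfg.penalty_weight * dev * dev
        dJ_docc = dr_docc.copy()
        dJ_docc[i_max] -= 2.0 * cfg.penalty_weight * dev

    gmat = np.zeros((L, 4))
    g_dG0 = 0.0
    for base_idx, d_docc_dE in terms:
        gE = dJ_docc[design.probe_idx] * d_docc_dE
        g_dG0 += float(gE.sum())
        for p in range(L):
            gmat[p] += np.bincount(base_idx[:, p], weights=gE, minlength=4)

    grad = np.empty_like(theta)
    grad[:4 * n_free] = gmat[free_pos].ravel()
    if cfg.fit_dG0:
        grad[-1] = g_dG0
    return -obj, -grad


def _run_fit(design: WindowDesign, signals: np.ndarray, start: EnergyMatrix,
             cfg: FitConfig, free_positions: Sequence[int] | None,
             seed: int) -> FitResult:
    y = np.asarray(signals, dtype=float)
    y_centered = y - y.mean()
    Svv = float(y_centered @ y_centered)
    if Svv < 1e-300:
        raise DegenerateObjectiveError("signals are constant; r is undefined")

    L = design.L
    free_pos = np.arange(L) if free_positions is None else np.asarray(
        sorted(free_positions), dtype=int)
    theta0 = start.ddG[free_pos].ravel()
    if cfg.fit_dG0:
        theta0 = np.append(theta0, start.dG0)

    res = optimize.minimize(
        _objective, theta0, jac=True, method="L-BFGS-B",
        args=(design, y_centered, Svv, start, free_pos, cfg),
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-8})

    ddG = start.ddG.copy()
    ddG[free_pos] = res.x[:4 * len(free_pos)].reshape(len(free_pos), 4)
    dG0 = float(res.x[-1]) if cfg.fit_dG0 else start.dG0
    matrix = normalize_matrix(ddG, dG0, protein_conc=start.protein_conc)
    occ = design.occupancies(matrix, cfg.ds_rule)
    r = _pearson_and_grad(occ, y_centered, Svv)[0]
    return FitResult(
        matrix=matrix,
        pearson_r=float(r),
        mae=float(_linear_map_mae(occ, y)),
        occupancies=occ,
        max_occupancy=float(occ.max()),
        converged=bool(res.success),
        n_iter=int(res.nit),
        seed=int(seed),
        objective=float(-res.fun),
        config=cfg,
    )


def _linear_map_mae(occ: np.ndarray, y: np.ndarray) -> float:
    """MAE after least-squares slope/offset mapping of occupancy to signal.

    Occupancy is in bound-proteins units while signals are normalized scores,
    so a free affine map is applied before computing the error."""
    A = np.column_stack([occ, np.ones_like(occ)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.mean(np.abs(A @ coef - y)))


# ---------------------------------------------------------------------------
# model / results


class BindingModel:
    """Thermodynamic occupancy model of probe binding data.

    Parameters
    ----------
    probes : ProbeSet
        Sequences and normalized binding signals.
    motif_length : int
        Length L of the energy matrix to fit.
    strandedness : str, optional
        Override the ProbeSet's strandedness.

    Examples
    --------
    >>> model = BindingModel(probes, motif_length=3)
    >>> result = model.fit(seed=1)
    >>> print(result.summary())
    """

    def __init__(self, probes: ProbeSet, motif_length: int = 3,
                 strandedness: str | None = None, **config):
        self.probes = probes
        self.config = FitConfig(motif_length=motif_length,
                                strandedness=strandedness or probes.strandedness,
                                **config)
        self._designs: dict[int, WindowDesign] = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, motif_length: int = 3,
                       seq_column: str = "sequence",
                       signal_column: str = "signal",
                       strandedness: str = "single", **config) -> "BindingModel":
        ps = ProbeSet.from_dataframe(df, seq_column, signal_column,
                                     strandedness=strandedness)
        return cls(ps, motif_length=motif_length, **config)

    def design(self, motif_length: int | None = None) -> WindowDesign:
        L = motif_length or self.config.motif_length
        if L not in self._designs:
            self._designs[L] = WindowDesign(self.probes.sequences, L,
                                            self.config.strandedness)
        return self._designs[L]

    def _start(self, cfg: FitConfig, seed: int) -> EnergyMatrix:
        if isinstance(cfg.start_matrix, EnergyMatrix):
            return cfg.start_matrix
        if cfg.start_matrix != "random":
            raise ValueError("start_matrix must be an EnergyMatrix or 'random'")
        rng = np.random.default_rng(seed)
        m = random_start_matrix(cfg.motif_length, rng, cfg.init_sd)
        return self.calibrate_dG0(m, cfg.occupancy_target)

    def fit(self, seed: int | None = None, start: EnergyMatrix | None = None,
            free_positions: Sequence[int] | None = None,
            **overrides) -> FitResult:
        """Locally optimize the energy matrix; returns a FitResult.

        ``free_positions`` restricts optimization to a subset of matrix
        columns (the rest stay at their start values), used when extending a
        frozen core motif.
        """
        cfg = replace(self.config, **overrides) if overrides else self.config
        if len(self.probes) < 3:
            raise ValueError("need at least 3 probes to fit")
        seed = cfg.seed if seed is None else int(seed)
        if start is not None:
            cfg = replace(cfg, start_matrix=start,
                          motif_length=start.length)
        start_m = self._start(cfg, seed)
        if start_m.length != cfg.motif_length:
            raise ValueError("start matrix length != motif_length")
        return _run_fit(self.design(cfg.motif_length), self.probes.signals,
                        start_m, cfg, free_positions, seed)

    def fit_multistart(self, n_restarts: int = 20, seed: int | None = None,
                       **overrides) -> list[FitResult]:
        """Independent fits from random starts, sorted by descending train r.

        Per-restart seeds are spawned deterministically from the master seed;
        ties on r break toward lower dG0, then lower seed."""
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        cfg = replace(self.config, **overrides) if overrides else self.config
        master = cfg.seed if seed is None else int(seed)
        ss = np.random.SeedSequence(master)
        seeds = [int(child.generate_state(1)[0] % _MAX_SEED)
                 for child in ss.spawn(n_restarts)]
        results = [self.fit(seed=s, **{**overrides, "start_matrix": "random"})
                   for s in seeds]
        results.sort(key=lambda fr: (-fr.pearson_r, fr.matrix.dG0, fr.seed))
        return results

    def predict(self, matrix: EnergyMatrix, probes: ProbeSet | None = None) -> np.ndarray:
        """Occupancy vector under ``matrix`` for these (or other) probes."""
        if probes is None or probes is self.probes:
            return self.design(matrix.length).occupancies(matrix,
                                                          self.config.ds_rule)
        design = WindowDesign(probes.sequences, matrix.length,
                              self.config.strandedness)
        return design.occupancies(matrix, self.config.ds_rule)

    def score(self, matrix: EnergyMatrix, probes: ProbeSet | None = None) -> float:
        """Pearson r between predicted occupancies and signals."""
        ps = self.probes if probes is None else probes
        occ = self.predict(matrix, probes)
        y = ps.signals
        if np.std(occ) == 0 or np.std(y) == 0:
            raise DegenerateObjectiveError(
                "zero variance in occupancies or signals; r is undefined")
        return float(np.corrcoef(occ, y)[0, 1])

    def calibrate_dG0(self, matrix: EnergyMatrix,
                      target_max_occupancy: float = 1.0) -> EnergyMatrix:
        """Set dG0 so the maximal per-probe occupancy hits the target.

        Occupancy is strictly decreasing in dG0, so monotone bracketing plus
        Brent root finding converges; the result is within 1e-6 of target."""
        if target_max_occupancy <= 0:
            raise ValueError("target_max_occupancy must be positive")
        design = self.design(matrix.length)
        counts = design.window_counts()
        limit = counts.max() if self.config.strandedness == "single" else counts.max()
        if target_max_occupancy >= limit:
            raise ValueError(
                f"target {target_max_occupancy} unreachable: occupancy is "
                f"bounded by {limit} windows per probe")

        def max_occ(dG0: float) -> float:
            return float(design.occupancies(matrix.with_dG0(dG0),
                                            self.config.ds_rule).max())

        lo, hi = -60.0, 60.0
        while max_occ(lo) < target_max_occupancy:
            lo *= 2
            if lo < -1e6:
                raise ValueError("target unreachable from below")
        while max_occ(hi) > target_max_occupancy:
            hi *= 2
        dG0 = optimize.brentq(
            lambda g: max_occ(g) - target_max_occupancy, lo, hi,
            xtol=1e-10, rtol=8.9e-16)
        return matrix.with_dG0(dG0)


# ---------------------------------------------------------------------------
# functional wrappers


def fit(ps: ProbeSet, cfg: FitConfig) -> FitResult:
    """Fit an energy matrix to a probe set with the given configuration."""
    model = BindingModel(ps, **_cfg_kwargs(cfg))
    return model.fit()


def multi_start_fit(ps: ProbeSet, cfg: FitConfig, n_restarts: int) -> list[FitResult]:
    model = BindingModel(ps, **_cfg_kwargs(cfg))
    return model.fit_multistart(n_restarts=n_restarts)


def predict(ps: ProbeSet, m: EnergyMatrix, ds_rule: str = "clip") -> np.ndarray:
    from .thermo import occupancy_vector
    return occupancy_vector(ps, m, ds_rule)


def score(ps: ProbeSet, m: EnergyMatrix, ds_rule: str = "clip") -> float:
    occ = predict(ps, m, ds_rule)
    y = ps.signals
    if np.std(occ) == 0 or np.std(y) == 0:
        raise DegenerateObjectiveError(
            "zero variance in occupancies or signals; r is undefined")
    return float(np.corrcoef(occ, y)[0, 1])


def calibrate_dG0(ps: ProbeSet, m: EnergyMatrix,
                  target_max_occupancy: float = 1.0,
                  ds_rule: str = "clip") -> EnergyMatrix:
    model = BindingModel(ps, motif_length=m.length, ds_rule=ds_rule)
    return model.calibrate_dG0(m, target_max_occupancy)


def _cfg_kwargs(cfg: FitConfig) -> dict:
    d = dict(cfg.__dict__)
    d.pop("motif_length", None)
    return {"motif_length": cfg.motif_length, **d}
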