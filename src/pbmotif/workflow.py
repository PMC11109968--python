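"""Explorative motif-analysis pipeline.

The pipeline mirrors how a scientist explores a new binding dataset:

1. split the probes 80/20 into train/test;
2. build a small balanced subset (top/bottom 4% by signal, capped at 1000)
   for fast initial searches;
3. choose a core motif length by cross-validation, maximizing
   (mean r)^2 / sqrt(L);
4. run many random-restart fits on the subset and inspect them with a 2D PCA
   of the energy matrices (reverse-complement twin clusters are an internal
   control for double-stranded probes), carrying the best fit forward;
5. refit on the full training set;
6. extend the core motif where flanking positions buy >= 2% correlation,
   grow borders whose terminal information exceeds 0.25 bit, prune border
   positions whose removal costs < 2%, refitting after each structural step;
7. report train/test correlations, a model-history table and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .logo import motif_report
from .probeio import ProbeSet, split_train_test
from .regressor import (BindingModel, DegenerateObjectiveError, FitConfig,
                        FitResult)
from .thermo import EnergyMatrix, normalize_matrix

logger = logging.getLogger(__name__)

_MAX_SEED = 2 ** 31


class WorkflowError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class WorkflowConfig:
    """Tunable thresholds of the explorative pipeline (defaults are the
    standard settings; see :func:`t7_config` for the custom-array preset)."""

    subset_quantile: float = 0.04
    subset_cap: int = 1000
    length_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    cv_folds: int = 5
    cv_repeats: int = 1
    n_restarts: int = 20
    extension_span: int = 3
    extension_gain: float = 0.02
    border_info_threshold: float = 0.25
    prune_drop_threshold: float = -0.02
    classification_sd_multiplier: float = 4.0
    seed: int = 0
    test_fraction: float = 0.2
    use_subset: bool = True
    relative_changes: bool = True  # 2% rules as relative delta-r/r
    # fit settings shared by every optimization in the pipeline
    fit_dG0: bool = False
    occupancy_target: float = 1.0
    penalty_weight: float = 10.0
    max_iter: int = 500
    tol: float = 1e-6
    ds_rule: str = "clip"

    def __post_init__(self):
        if not 0 < self.subset_quantile < 0.5:
            raise ValueError("subset_quantile must be in (0, 0.5)")
        for name in ("subset_cap", "cv_folds", "n_restarts", "extension_span"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.extension_gain <= 0 or self.border_info_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.length_grid:
            raise ValueError("length_grid must be non-empty")

    def fit_kwargs(self) -> dict:
        return dict(fit_dG0=self.fit_dG0,
                    occupancy_target=self.occupancy_target,
                    penalty_weight=self.penalty_weight,
                    max_iter=self.max_iter, tol=self.tol, ds_rule=self.ds_rule)


def t7_config(**overrides) -> WorkflowConfig:
    """Preset for the custom primase array analysis: no subset (the array is
    small), repeated cross-validation, dG0 in the fit with the max-occupancy
    penalty targeting 1 bound protein per probe."""
    base = dict(use_subset=False, cv_repeats=10, n_restarts=200,
                length_grid=(2, 3, 4, 5, 6), fit_dG0=True,
                occupancy_target=1.0)
    base.update(overrides)
    return WorkflowConfig(**base)


def _rel_delta(new_r: float, base_r: float, relative: bool) -> float:
    return (new_r - base_r) / abs(base_r) if relative else new_r - base_r


def _model(ps: ProbeSet, L: int, cfg: WorkflowConfig, **kw) -> BindingModel:
    return BindingModel(ps, motif_length=L, **{**cfg.fit_kwargs(), **kw})


# ---------------------------------------------------------------------------
# stages


def build_subset(ps: ProbeSet, cfg: WorkflowConfig,
                 seed: int | None = None) -> ProbeSet:
    """Balanced top/bottom-quantile subset, downsampled to the cap."""
    n = len(ps)
    if n < 50:
        raise ValueError("need >= 50 probes to build a subset")
    n_q = int(np.floor(cfg.subset_quantile * n))
    if n_q < 1 or 2 * n_q > n:
        raise ValueError("quantiles overlap: too few probes for the subset")
    order = np.argsort(ps.signals, kind="stable")
    bottom = order[:n_q]
    top = order[-n_q:]
    half = cfg.subset_cap // 2
    if n_q > half:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        bottom = rng.choice(bottom, size=half, replace=False)
        top = rng.choice(top, size=half, replace=False)
    idx = np.sort(np.concatenate([bottom, top]))
    return ps.subset(idx)


def select_motif_length(ps: ProbeSet, cfg: WorkflowConfig
                        ) -> tuple[int, pd.DataFrame]:
    """Cross-validated motif-length scan; picks argmax of (mean r)^2 / sqrt(L).

    Returns the chosen length and the per-length table (mean/sd of train and
    validation r over folds) for plotting."""
    from sklearn.model_selection import KFold

    rows = []
    n = len(ps)
    min_len = min(len(s) for s in ps.sequences)
    ss = np.random.SeedSequence(cfg.seed)
    for L, child in zip(cfg.length_grid, ss.spawn(len(cfg.length_grid))):
        if L > min_len:
            logger.warning("skipping motif length %d > shortest probe", L)
            continue
        r_train, r_val = [], []
        fold_seeds = [int(s.generate_state(1)[0] % _MAX_SEED)
                      for s in child.spawn(cfg.cv_repeats * cfg.cv_folds)]
        si = 0
        for rep in range(cfg.cv_repeats):
            kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
                       random_state=fold_seeds[si] % (2 ** 32 - 1))
            for tr_idx, va_idx in kf.split(np.arange(n)):
                fold_seed = fold_seeds[si]
                si += 1
                try:
                    train = ps.subset(tr_idx)
                    model = _model(train, L, cfg)
                    res = model.fit(seed=fold_seed)
                    r_train.append(res.pearson_r)
                    r_val.append(model.score(res.matrix, ps.subset(va_idx)))
                except (ValueError, DegenerateObjectiveError) as e:
                    logger.warning("fold failed at L=%d: %s", L, e)
                    r_train.append(np.nan)
                    r_val.append(np.nan)
        if np.all(np.isnan(r_val)):
            continue
        mean_val = float(np.nanmean(r_val))
        rows.append({
            "motif_length": L,
            "mean_r_train": float(np.nanmean(r_train)),
            "sd_r_train": float(np.nanstd(r_train)),
            "mean_r_val": mean_val,
            "sd_r_val": float(np.nanstd(r_val)),
            "criterion": mean_val ** 2 / np.sqrt(L),
        })
    if not rows:
        raise ValueError("no feasible motif length in the grid")
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["criterion"].idxmax(), "motif_length"])
    return chosen, table


@dataclass
class ClusterReport:
    """2D PCA of restart energy matrices plus the chosen best fit."""

    coordinates: np.ndarray        # (n_restarts, 2)
    explained_variance_ratio: np.ndarray
    best: FitResult
    rc_twin_present: bool | None   # None for single-stranded data
    pearson_rs: np.ndarray | None = None


def cluster_restarts(results: list[FitResult],
                     rc_tol: float = 0.3) -> ClusterReport:
    """PCA embedding of multi-start fits (gauge-projected matrices, so
    gauge-equivalent motifs coincide); flags reverse-complement twins for
    double-stranded fits."""
    if len(results) < 3:
        raise ValueError("need >= 3 fits for a PCA comparison")
    lengths = {fr.matrix.length for fr in results}
    if len(lengths) != 1:
        raise ValueError(f"mixed motif lengths in restart list: {lengths}")
    from sklearn.decomposition import PCA

    X = np.stack([fr.matrix.normalized().ddG.ravel() for fr in results])
    pca = PCA(n_components=2)
    if np.allclose(X, X[0]):
        coords = np.zeros((len(results), 2))
        evr = np.zeros(2)
    else:
        coords = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    best = max(results, key=lambda fr: fr.pearson_r)
    ds = any(fr.config is not None and fr.config.strandedness == "double"
             for fr in results)
    rc_twin = None
    if ds:
        rc = best.matrix.normalized().reverse_complement().ddG.ravel()
        scale = max(np.linalg.norm(rc), 1e-12)
        rc_twin = bool(any(
            np.linalg.norm(x - rc) / scale < rc_tol
            for fr, x in zip(results, X) if fr is not best))
    return ClusterReport(coords, evr, best, rc_twin,
                         np.array([fr.pearson_r for fr in results]))


def extend_motif(ps: ProbeSet, core: FitResult, cfg: WorkflowConfig,
                 seed: int | None = None) -> FitResult:
    """Try flanking positions (core frozen, new column fitted from zeros,
    nearest first, 5' before 3'); positions gaining >= extension_gain in r
    are kept and the combined matrix is jointly refit."""
    seed = cfg.seed if seed is None else int(seed)
    base_model = _model(ps, core.matrix.length, cfg)
    r0 = base_model.score(core.matrix)
    r_base = r0  # updated as extensions are accepted
    current = core.matrix.normalized()
    n_added_5, n_added_3 = 0, 0
    for side in ("5prime", "3prime"):
        for _ in range(cfg.extension_span):
            zero = np.zeros((1, 4))
            if side == "5prime":
                cand = np.vstack([zero, current.ddG])
                free = [0]
            else:
                cand = np.vstack([current.ddG, zero])
                free = [cand.shape[0] - 1]
            start = EnergyMatrix(cand, current.dG0)
            try:
                model = _model(ps, start.length, cfg)
                res = model.fit(seed=seed, start=start, free_positions=free)
            except ValueError as e:
                logger.warning("extension beyond probe bounds skipped: %s", e)
                break
            gain = _rel_delta(res.pearson_r, r_base, cfg.relative_changes)
            if gain >= cfg.extension_gain:
                current = res.matrix
                r_base = res.pearson_r
                if side == "5prime":
                    n_added_5 += 1
                else:
                    n_added_3 += 1
            else:
                break
    if n_added_5 == 0 and n_added_3 == 0:
        return core
    model = _model(ps, current.length, cfg)
    final = model.fit(seed=seed, start=current)
    logger.info("extension added %d x 5' and %d x 3' positions (r %.4f -> %.4f)",
                n_added_5, n_added_3, r0, final.pearson_r)
    return final


def grow_borders(ps: ProbeSet, current: FitResult, cfg: WorkflowConfig,
                 seed: int | None = None) -> FitResult:
    """Add one zero-initialized position per side where the terminal
    position's information content exceeds the border threshold, then refit."""
    seed = cfg.seed if seed is None else int(seed)
    report = motif_report(current.matrix)
    grow_5 = report.info_per_position[0] > cfg.border_info_threshold
    grow_3 = report.info_per_position[-1] > cfg.border_info_threshold
    if not (grow_5 or grow_3):
        return current
    blocks = []
    if grow_5:
        blocks.append(np.zeros((1, 4)))
    blocks.append(current.matrix.ddG)
    if grow_3:
        blocks.append(np.zeros((1, 4)))
    start = EnergyMatrix(np.vstack(blocks), current.matrix.dG0)
    try:
        model = _model(ps, start.length, cfg)
        return model.fit(seed=seed, start=start)
    except ValueError as e:
        logger.warning("border growth skipped: %s", e)
        return current


def prune_positions(ps: ProbeSet, current: FitResult, cfg: WorkflowConfig,
                    seed: int | None = None) -> FitResult:
    """Drop contiguous border positions whose column contributes < 2% of r
    (evaluated by zeroing the column), then refit at the reduced length."""
    seed = cfg.seed if seed is None else int(seed)
    m = current.matrix
    L = m.length
    if L < 2:
        raise ValueError("cannot prune a single-position motif")
    model = _model(ps, L, cfg)
    r0 = model.score(m)
    droppable = np.zeros(L, dtype=bool)
    for p in range(L):
        ddG = m.ddG.copy()
        ddG[p] = 0.0
        try:
            rp = model.score(EnergyMatrix(ddG, m.dG0))
        except DegenerateObjectiveError:
            continue
        droppable[p] = _rel_delta(rp, r0, cfg.relative_changes) > cfg.prune_drop_threshold
    lo = 0
    while lo < L and droppable[lo]:
        lo += 1
    hi = L
    while hi > lo and droppable[hi - 1]:
        hi -= 1
    if lo == 0 and hi == L:
        return current
    if lo >= hi:
        raise ValueError("pruning would drop every position of the motif")
    start = EnergyMatrix(m.ddG[lo:hi].copy(), m.dG0)
    model = _model(ps, start.length, cfg)
    res = model.fit(seed=seed, start=start)
    logger.info("pruned to positions [%d, %d) (r %.4f -> %.4f)",
                lo, hi, r0, res.pearson_r)
    return res


def classification_threshold(ps: ProbeSet, cfg: WorkflowConfig) -> float:
    """Binder/non-binder threshold: mean + k * sd of all signals."""
    if len(ps) < 2:
        raise ValueError("need >= 2 probes")
    y = ps.signals
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("zero signal variance: threshold undefined")
    return float(y.mean() + cfg.classification_sd_multiplier * sd)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class WorkflowReport:
    """Everything the pipeline produced, for inspection and plotting."""

    final: FitResult
    train_r: float
    test_r: float
    history: pd.DataFrame
    length_table: pd.DataFrame
    chosen_length: int
    cluster: ClusterReport
    threshold: float
    config: WorkflowConfig
    train: ProbeSet
    test: ProbeSet


def run_workflow(ps: ProbeSet, cfg: WorkflowConfig | None = None,
                 outdir=None) -> WorkflowReport:
    """Run the full explorative pipeline on a probe set.

    Writes diagnostics (matrix JSON, history TSV, plots) under ``outdir``
    when given.  Every stage is deterministic for a fixed ``cfg.seed``."""
    cfg = cfg or WorkflowConfig()
    history: list[dict] = []

    def run_stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise WorkflowError(name, e) from e

    def record(stage: str, fr: FitResult, train_ps: ProbeSet, test_ps: ProbeSet):
        model = _model(train_ps, fr.matrix.length, cfg)
        try:
            test_r = model.score(fr.matrix, test_ps)
        except (ValueError, DegenerateObjectiveError):
            test_r = np.nan
        history.append({"stage": stage, "motif_length": fr.matrix.length,
                        "train_r": fr.pearson_r, "test_r": test_r})
        return test_r

    train, test = run_stage("split", split_train_test, ps,
                            cfg.test_fraction, cfg.seed)
    subset = (run_stage("subset", build_subset, train, cfg)
              if cfg.use_subset else train)

    # quick single fit at a mid-grid length as a data-integrity check
    mid_L = int(cfg.length_grid[len(cfg.length_grid) // 2])
    quick = run_stage("integrity",
                      lambda: _model(subset, mid_L, cfg).fit(seed=cfg.seed))
    record("integrity", quick, subset, test)

    chosen_L, length_table = run_stage("length_selection",
                                       select_motif_length, subset, cfg)
    restarts = run_stage("multistart", lambda: _model(subset, chosen_L, cfg)
                         .fit_multistart(cfg.n_restarts, seed=cfg.seed))
    cluster = run_stage("pca", cluster_restarts, restarts)
    record("subset_best", cluster.best, subset, test)

    # the restart motifs are re-scored on the full training set and the best
    # there (not on the subset) is carried forward
    def pick_carryover():
        full_model = _model(train, chosen_L, cfg)
        scores = []
        for fr in restarts:
            try:
                scores.append(full_model.score(fr.matrix))
            except DegenerateObjectiveError:
                scores.append(-np.inf)
        return restarts[int(np.argmax(scores))]

    carry = run_stage("train_rescore", pick_carryover)

    core = run_stage("train_refit", lambda: _model(train, chosen_L, cfg)
                     .fit(seed=cfg.seed, start=carry.matrix))
    record("core", core, train, test)

    extended = run_stage("extend", extend_motif, train, core, cfg)
    record("extended", extended, train, test)
    grown = run_stage("grow", grow_borders, train, extended, cfg)
    record("grown", grown, train, test)
    pruned = run_stage("prune", prune_positions, train, grown, cfg)
    test_r = record("final", pruned, train, test)

    threshold = run_stage("threshold", classification_threshold, ps, cfg)
    report = WorkflowReport(
        final=pruned, train_r=pruned.pearson_r, test_r=float(test_r),
        history=pd.DataFrame(history), length_table=length_table,
        chosen_length=chosen_L, cluster=cluster, threshold=threshold,
        config=cfg, train=train, test=test)
    if outdir is not None:
        save_report(report, outdir)
    return report


def save_report(report: WorkflowReport, outdir) -> None:
    """Write matrix JSON, history/length tables and diagnostic figures."""
    import os

    from .logo import render_logos

    os.makedirs(outdir, exist_ok=True)
    report.final.matrix.save(os.path.join(outdir, "energy_matrix.json"))
    report.history.to_csv(os.path.join(outdir, "history.tsv"), sep="\t",
                          index=False)
    report.length_table.to_csv(os.path.join(outdir, "length_selection.tsv"),
                               sep="\t", index=False)
    render_logos(report.final.matrix, os.path.join(outdir, "motif"))
    plot_signal_histogram(report.train, report.threshold,
                          os.path.join(outdir, "signal_histogram.png"))
    plot_energy_histogram(report.train, report.final.matrix,
                          os.path.join(outdir, "energy_histogram.png"))
    model = _model(report.train, report.final.matrix.length, report.config)
    occ = model.predict(report.final.matrix)
    plot_occupancy_heatmap(occ, report.train.signals, report.threshold,
                           os.path.join(outdir, "occupancy_vs_signal.png"))
    plot_length_selection(report.length_table,
                          os.path.join(outdir, "length_selection.png"))
    plot_pca(report.cluster, os.path.join(outdir, "restart_pca.png"))


# ---------------------------------------------------------------------------
# diagnostics


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_signal_histogram(ps: ProbeSet, threshold: float | None, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(ps.signals, bins=50, color="steelblue")
    if threshold is not None:
        ax.axvline(threshold, color="red", lw=1, label="classification threshold")
        ax.legend(fontsize=7)
    ax.set_xlabel("binding signal")
    ax.set_ylabel("probes")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_energy_histogram(ps: ProbeSet, m: EnergyMatrix, path) -> None:
    """Distribution of window binding energies over all probes, with a fitted
    normal curve and the unspecific energy dG0 marked."""
    from scipy import stats

    from .thermo import WindowDesign

    plt = _plt()
    design = WindowDesign(ps.sequences, m.length, ps.strandedness)
    E = design._window_energies(design.base_idx_fw, m.ddG, m.dG0)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(E, bins=60, density=True, color="grey")
    mu, sd = float(E.mean()), float(E.std())
    if sd > 0:
        x = np.linspace(E.min(), E.max(), 200)
        ax.plot(x, stats.norm.pdf(x, mu, sd), "k-", lw=1)
    ax.axvline(m.dG0, color="red", lw=1, label=r"$\Delta G_0$")
    ax.set_xlabel("window energy (RT)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_occupancy_heatmap(occ: np.ndarray, signals: np.ndarray,
                           threshold: float | None, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    h = ax.hist2d(occ, signals, bins=40, cmap="viridis", cmin=1)
    fig.colorbar(h[3], ax=ax, label="probes")
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xlabel("predicted occupancy (bound/probe)")
    ax.set_ylabel("binding signal")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_length_selection(table: pd.DataFrame, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(table["motif_length"], table["mean_r_val"],
                yerr=table["sd_r_val"], marker="o", label="validation r")
    ax.errorbar(table["motif_length"], table["mean_r_train"],
                yerr=table["sd_r_train"], marker="s", ls="--", label="train r")
    ax2 = ax.twinx()
    ax2.plot(table["motif_length"], table["criterion"], "k:",
             label=r"$r^2/\sqrt{L}$")
    ax.set_xlabel("motif length")
    ax.set_ylabel("Pearson r")
    ax2.set_ylabel(r"$r^2/\sqrt{L}$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca(cluster: ClusterReport, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    colors = (cluster.pearson_rs if cluster.pearson_rs is not None
              else np.zeros(len(cluster.coordinates)))
    sc = ax.scatter(cluster.coordinates[:, 0], cluster.coordinates[:, 1],
                    c=colors, cmap="viridis", s=18)
    fig.colorbar(sc, ax=ax, label="train r")
    ax.set_xlabel(f"PC1 ({cluster.explained_variance_ratio[0]:.0%})")
    ax.set_ylabel(f"PC2 ({cluster.explained_variance_ratio[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
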