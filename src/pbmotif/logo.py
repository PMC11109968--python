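"""Motif representations: frequency matrices, information content, logos and
the information-distance metric between motifs.

An energy matrix maps to base frequencies by Boltzmann weighting,
``f ~ exp(-beta * ddG)`` per position (beta = 1 in RT units by default), and
frequencies map to per-position information against a uniform background,
``IC_p = 2 + sum_b f_pb log2 f_pb`` bits.  Letter heights in an information
logo are the per-base contributions ``f_pb * IC_p``; the distance between two
motifs is the Euclidean norm of the difference of those contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .thermo import BASES, EnergyMatrix, normalize_matrix

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


@dataclass(frozen=True)
class MotifReport:
    """Frequency/information view of an energy matrix."""

    frequency: np.ndarray          # (L, 4), rows sum to 1
    info_per_position: np.ndarray  # bits
    total_info: float              # bits
    source: EnergyMatrix | None = None
    beta: float = 1.0

    @property
    def length(self) -> int:
        return self.frequency.shape[0]

    @property
    def contributions(self) -> np.ndarray:
        """Per-base information contributions f * IC (logo letter heights)."""
        return self.frequency * self.info_per_position[:, None]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequency, axis=1))


def energy_to_frequency(m: EnergyMatrix, beta: float = 1.0) -> np.ndarray:
    """Boltzmann frequency matrix of an energy matrix.

    f[p, b] = exp(-beta * ddG[p, b]) / sum_b' exp(-beta * ddG[p, b'])
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    w = -beta * m.ddG
    w -= w.max(axis=1, keepdims=True)  # overflow-safe softmax
    e = np.exp(w)
    return e / e.sum(axis=1, keepdims=True)


def frequency_to_energy(frequency: np.ndarray, beta: float = 1.0,
                        dG0: float = 0.0, floor: float = 1e-12) -> EnergyMatrix:
    """Inverse of :func:`energy_to_frequency` (gauge-projected).

    Zero frequencies are floored before the log so near-deterministic motifs
    stay finite (they get large but finite unfavourable energies)."""
    f = np.clip(np.asarray(frequency, dtype=float), floor, None)
    return normalize_matrix(-np.log(f) / beta, dG0)


def information_content(frequency: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-position and total information (bits) against a uniform background.

    IC_p = 2 + sum_b f log2 f, with 0*log(0) = 0."""
    f = np.asarray(frequency, dtype=float)
    if f.ndim != 2 or f.shape[1] != 4:
        raise ValueError(f"expected (L, 4) frequency matrix, got {f.shape}")
    if np.any(np.abs(f.sum(axis=1) - 1.0) > 1e-6) or np.any(f < -1e-12):
        raise ValueError("frequency rows must be stochastic (sum to 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    per_pos = 2.0 + plogp.sum(axis=1)
    per_pos = np.clip(per_pos, 0.0, 2.0)
    return per_pos, float(per_pos.sum())


def motif_report(m: EnergyMatrix, beta: float = 1.0) -> MotifReport:
    freq = energy_to_frequency(m, beta)
    per_pos, total = information_content(freq)
    return MotifReport(freq, per_pos, total, source=m, beta=beta)


# ---------------------------------------------------------------------------
# motif distance


def motif_distance(a: MotifReport, b: MotifReport) -> float:
    """Root of the summed squared differences of per-base information
    contributions; a Euclidean metric on logos of equal length."""
    if a.length != b.length:
        raise ValueError(
            "motif lengths differ; use aligned_motif_distance for "
            "shift-tolerant comparison")
    return float(np.sqrt(((a.contributions - b.contributions) ** 2).sum()))


def aligned_motif_distance(a: MotifReport, b: MotifReport) -> tuple[float, int]:
    """Minimal motif distance over zero-padded relative offsets.

    Slides ``b`` against ``a`` and returns ``(distance, offset)`` where offset
    is the shift of b's first position relative to a's (positions outside
    either motif contribute zero information)."""
    ca, cb = a.contributions, b.contributions
    La, Lb = a.length, b.length
    best = (np.inf, 0)
    for off in range(-(Lb - 1), La):
        span = max(La, off + Lb) - min(0, off)
        pa = np.zeros((span, 4))
        pb = np.zeros((span, 4))
        sa = -min(0, off)
        pa[sa:sa + La] = ca
        pb[sa + off:sa + off + Lb] = cb
        d = float(np.sqrt(((pa - pb) ** 2).sum()))
        if d < best[0] - 1e-15:
            best = (d, off)
    return best


# ---------------------------------------------------------------------------
# rendering


def _letter_patches(ax, letter: str, x: float, y: float, width: float,
                    height: float, color: str):
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if height <= 0:
        return
    tp = TextPath((0, 0), letter, size=1.0,
                  prop=FontProperties(family="DejaVu Sans", weight="bold"))
    bb = tp.get_extents()
    transform = (Affine2D()
                 .translate(-bb.x0, -bb.y0)
                 .scale(width / bb.width, height / bb.height)
                 .translate(x, y))
    ax.add_patch(PathPatch(tp.transformed(transform), facecolor=color,
                           edgecolor="none"))


def _stacked_letters(ax, heights: np.ndarray, signed: bool = False):
    """Draw a logo: per position, letters stacked by |height|; with
    ``signed`` negative heights hang below the axis."""
    L = heights.shape[0]
    for p in range(L):
        order = np.argsort(np.abs(heights[p]))
        y_pos, y_neg = 0.0, 0.0
        for b in order:
            h = heights[p, b]
            if abs(h) < 1e-9:
                continue
            letter = BASES[b]
            if signed and h < 0:
                y_neg -= abs(h)
                _letter_patches(ax, letter, p + 0.05, y_neg, 0.9, abs(h),
                                _BASE_COLORS[letter])
            else:
                _letter_patches(ax, letter, p + 0.05, y_pos, 0.9, abs(h),
                                _BASE_COLORS[letter])
                y_pos += abs(h)
    ax.set_xlim(0, L)
    ax.set_xticks(np.arange(L) + 0.5, [str(i) for i in range(L)])


def render_logos(m: EnergyMatrix, path_prefix, beta: float = 1.0,
                 formats: tuple[str, ...] = ("png",)) -> list[str]:
    """Write an information logo and an energy logo for a matrix.

    Files are named ``<prefix>_info.<fmt>`` and ``<prefix>_energy.<fmt>``;
    the energy logo draws -ddG so favourable bases point up."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    report = motif_report(m, beta)
    written = []

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * m.length, 2.4))
    _stacked_letters(ax, report.contributions)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    fig.tight_layout()
    for fmt in formats:
        out = f"{path_prefix}_info.{fmt}"
        fig.savefig(out, metadata=_clean_metadata(fmt))
        written.append(out)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * m.length, 2.4))
    _stacked_letters(ax, -m.ddG, signed=True)
    span = max(1.0, float(np.abs(m.ddG).max()) * 1.1)
    ax.set_ylim(-span, span)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel(r"$-\Delta\Delta G$ (RT)")
    fig.tight_layout()
    for fmt in formats:
        out = f"{path_prefix}_energy.{fmt}"
        fig.savefig(out, metadata=_clean_metadata(fmt))
        written.append(out)
    plt.close(fig)
    return written


def _clean_metadata(fmt: str):
    # strip creation timestamps so re-renders are byte-stable
    if fmt == "png":
        return {"Software": "pbmotif"}
    if fmt == "svg":
        return {"Date": None}
    return None


# ---------------------------------------------------------------------------
# export


def write_meme(report: MotifReport, path, name: str = "motif") -> None:
    """Write the frequency matrix in MEME minimal motif format."""
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {report.length}",
    ]
    for row in report.frequency:
        lines.append(" ".join(f"{x:.6f}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_frequency_tsv(report: MotifReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(BASES) + "\tinfo_bits\n")
        for p in range(report.length):
            row = "\t".join(f"{x:.10g}" for x in report.frequency[p])
            fh.write(f"{p}\t{row}\t{report.info_per_position[p]:.10g}\n")
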