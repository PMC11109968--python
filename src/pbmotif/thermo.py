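"""Thermodynamic core: energy matrices, binding-site windows and Langmuir occupancies.

The binding model treats every length-``L`` subsequence (window) of a probe as an
independent potential binding site.  A window's standard free energy of
association is

    dG = dG0 + sum_p ddG[p, base_p]        (RT units, RT == 1)

where ``ddG`` is an L x 4 position/base-specific energy matrix constrained to
sum to zero over the four bases at every position (the zero-sum gauge), and
``dG0`` is the unspecific affinity.  The fractional occupancy of the window
follows the Langmuir isotherm

    occ = c / (c + exp(dG)),    KD = exp(dG)

with ``c`` the (dimensionless) protein concentration, and the probe occupancy is
the sum of its window occupancies.  For double-stranded probes the forward and
reverse-complement occupancies at each offset are combined with a cap at one
bound protein per site.

Only the difference ``dG0 - ln c`` is identifiable from relative binding data,
so ``c`` defaults to 1 and is never fitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement permutation of the A,C,G,T column order
COMPLEMENT = np.array([3, 2, 1, 0])

_ZERO_SUM_TOL = 1e-9


class SequenceError(ValueError):
    """A nucleotide sequence contains characters outside A/C/G/T."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int8 array of base indices."""
    if not sequence:
        raise SequenceError("empty sequence")
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(codes.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[codes == ord(base)] = idx
    if (out < 0).any():
        bad = sequence[int(np.argmax(out < 0))]
        raise SequenceError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def reverse_complement(sequence: str) -> str:
    codes = encode_sequence(sequence)
    return decode_sequence((3 - codes)[::-1])


@dataclass(frozen=True)
class EnergyMatrix:
    """Position/base-specific binding energies in RT units.

    Parameters
    ----------
    ddG : (L, 4) array
        Base- and position-specific energy contributions, columns ordered
        A, C, G, T.  Kept in the zero-sum gauge (each row sums to 0).
    dG0 : float
        Unspecific standard free energy; sets overall affinity.
    protein_conc : float
        Dimensionless protein concentration of the Langmuir isotherm.
    """

    ddG: np.ndarray
    dG0: float = 0.0
    protein_conc: float = 1.0

    def __post_init__(self):
        ddG = np.asarray(self.ddG, dtype=float)
        if ddG.ndim != 2 or ddG.shape[1] != 4 or ddG.shape[0] < 1:
            raise ValueError(f"ddG must be (L, 4) with L >= 1, got {ddG.shape}")
        if not np.all(np.isfinite(ddG)) or not np.isfinite(self.dG0):
            raise ValueError("energy matrix entries must be finite")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        object.__setattr__(self, "ddG", ddG)

    @property
    def length(self) -> int:
        return self.ddG.shape[0]

    def is_normalized(self, tol: float = _ZERO_SUM_TOL) -> bool:
        return bool(np.all(np.abs(self.ddG.sum(axis=1)) <= tol))

    def normalized(self) -> "EnergyMatrix":
        """Project into the zero-sum gauge, absorbing row means into dG0."""
        return normalize_matrix(self.ddG, self.dG0, protein_conc=self.protein_conc)

    def reverse_complement(self) -> "EnergyMatrix":
        """Matrix describing the same motif read on the opposite strand."""
        return replace(self, ddG=self.ddG[::-1, COMPLEMENT].copy())

    def with_dG0(self, dG0: float) -> "EnergyMatrix":
        return replace(self, dG0=float(dG0))

    # --- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "length": self.length,
                "dG0": self.dG0,
                "protein_conc": self.protein_conc,
                "base_order": BASES,
                "ddG": self.ddG.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnergyMatrix":
        d = json.loads(text)
        if d.get("base_order", BASES) != BASES:
            raise ValueError("unsupported base order")
        return cls(np.array(d["ddG"], dtype=float), float(d["dG0"]),
                   float(d.get("protein_conc", 1.0)))

    def to_text(self) -> str:
        """Plain-text format: a header line then one row per position."""
        lines = [f"# length={self.length} dG0={self.dG0!r} "
                 f"protein_conc={self.protein_conc!r} bases={BASES}"]
        for row in self.ddG:
            lines.append("\t".join(repr(float(x)) for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "EnergyMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        header = lines[0]
        if not header.startswith("#"):
            raise ValueError("missing header line")
        fields = dict(tok.split("=", 1) for tok in header[1:].split())
        if fields.get("bases", BASES) != BASES:
            raise ValueError("unsupported base order")
        ddG = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return cls(ddG, float(fields["dG0"]), float(fields.get("protein_conc", 1.0)))

    def save(self, path, fmt: str = "json") -> None:
        text = self.to_json() if fmt == "json" else self.to_text()
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "EnergyMatrix":
        with open(path) as fh:
            text = fh.read()
        return cls.from_json(text) if text.lstrip().startswith("{") else cls.from_text(text)


def normalize_matrix(raw: np.ndarray, dG0: float = 0.0, *,
                     protein_conc: float = 1.0) -> EnergyMatrix:
    """Gauge-project a raw L x 4 energy matrix into the zero-sum form.

    The per-position mean is subtracted from each row and the sum of removed
    means is added to ``dG0``, so every window's total energy — and hence every
    occupancy — is unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 4:
        raise ValueError(f"expected (L, 4) matrix, got {raw.shape}")
    if not (np.all(np.isfinite(raw)) and np.isfinite(dG0)):
        raise ValueError("non-finite energies")
    means = raw.mean(axis=1)
    return EnergyMatrix(raw - means[:, None], float(dG0 + means.sum()),
                        protein_conc=protein_conc)


def random_start_matrix(L: int, rng: np.random.Generator,
                        sd: float = 0.5) -> EnergyMatrix:
    """I.i.d. normal entries (sd in RT units), gauge-projected; dG0 = 0."""
    return normalize_matrix(rng.normal(0.0, sd, size=(L, 4)), 0.0)


# ---------------------------------------------------------------------------
# windows


@dataclass(frozen=True)
class SubsequenceWindow:
    """One candidate binding site: a length-L window of a probe."""

    probe_id: str
    offset: int
    strand: str  # "fw" or "rc"
    encoded: np.ndarray  # (L, 4) one-hot

    @property
    def sequence(self) -> str:
        return decode_sequence(np.argmax(self.encoded, axis=1))


def _one_hot(codes: np.ndarray) -> np.ndarray:
    out = np.zeros((codes.size, 4))
    out[np.arange(codes.size), codes] = 1.0
    return out


def enumerate_windows(sequence: str, L: int, strandedness: str = "single",
                      probe_id: str = "") -> list[SubsequenceWindow]:
    """All length-L windows of ``sequence`` (and their reverse complements
    for double-stranded probes), sliding by one nucleotide."""
    codes = encode_sequence(sequence)
    if L > codes.size:
        raise ValueError(f"motif length {L} exceeds sequence length {codes.size}")
    if L < 1:
        raise ValueError("motif length must be >= 1")
    windows = []
    for off in range(codes.size - L + 1):
        sub = codes[off:off + L]
        windows.append(SubsequenceWindow(probe_id, off, "fw", _one_hot(sub)))
    if strandedness == "double":
        for off in range(codes.size - L + 1):
            sub = (3 - codes[off:off + L])[::-1]
            windows.append(SubsequenceWindow(probe_id, off, "rc", _one_hot(sub)))
    elif strandedness != "single":
        raise ValueError(f"unknown strandedness {strandedness!r}")
    return windows


class WindowDesign:
    """Vectorized window encoding of a probe set for a fixed motif length.

    Precomputes, for every window, the base index at each motif position and
    the probe each window belongs to, so occupancies and their derivatives can
    be evaluated with array operations during fitting.
    """

    def __init__(self, sequences: Sequence[str], L: int,
                 strandedness: str = "single"):
        if strandedness not in ("single", "double"):
            raise ValueError(f"unknown strandedness {strandedness!r}")
        self.L = int(L)
        self.strandedness = strandedness
        self.n_probes = len(sequences)
        fw_rows, rc_rows, probe_idx = [], [], []
        for i, seq in enumerate(sequences):
            codes = encode_sequence(seq)
            n = codes.size - self.L + 1
            if n < 1:
                raise ValueError(
                    f"probe {i} shorter ({codes.size} nt) than motif length {L}")
            view = np.lib.stride_tricks.sliding_window_view(codes, self.L)
            fw_rows.append(view)
            if strandedness == "double":
                rc_rows.append((3 - view)[:, ::-1])
            probe_idx.append(np.full(n, i, dtype=np.intp))
        self.base_idx_fw = np.ascontiguousarray(np.concatenate(fw_rows))
        self.probe_idx = np.concatenate(probe_idx)
        self.base_idx_rc = (np.ascontiguousarray(np.concatenate(rc_rows))
                            if strandedness == "double" else None)

    @property
    def n_windows(self) -> int:
        n = self.base_idx_fw.shape[0]
        return 2 * n if self.base_idx_rc is not None else n

    def window_counts(self) -> np.ndarray:
        """Forward windows per probe."""
        return np.bincount(self.probe_idx, minlength=self.n_probes)

    def _window_energies(self, base_idx: np.ndarray, ddG: np.ndarray,
                         dG0: float) -> np.ndarray:
        pos = np.arange(self.L)
        return dG0 + ddG[pos[None, :], base_idx].sum(axis=1)

    def occupancies(self, m: EnergyMatrix, ds_rule: str = "clip") -> np.ndarray:
        """Per-probe occupancies under matrix ``m``."""
        occ, _ = self.occupancies_and_terms(m, ds_rule)
        return occ

    def occupancies_and_terms(self, m: EnergyMatrix, ds_rule: str = "clip"):
        """Per-probe occupancies plus per-window derivative terms.

        Returns ``(probe_occ, terms)`` where ``terms`` is a list of
        ``(base_idx, d_occ_d_energy)`` pairs, one per strand, giving for each
        window the derivative of its contribution to the probe occupancy with
        respect to that window's total energy.
        """
        if m.length != self.L:
            raise ValueError(f"matrix length {m.length} != design length {self.L}")
        c = m.protein_conc
        E_fw = self._window_energies(self.base_idx_fw, m.ddG, m.dG0)
        o_fw = c / (c + np.exp(np.minimum(E_fw, 700.0)))
        d_fw = -o_fw * (1.0 - o_fw)  # d occ / d energy
        if self.base_idx_rc is None:
            contrib = o_fw
            terms = [(self.base_idx_fw, d_fw)]
        else:
            E_rc = self._window_energies(self.base_idx_rc, m.ddG, m.dG0)
            o_rc = c / (c + np.exp(np.minimum(E_rc, 700.0)))
            d_rc = -o_rc * (1.0 - o_rc)
            if ds_rule == "clip":
                total = o_fw + o_rc
                contrib = np.minimum(total, 1.0)
                open_site = (total < 1.0).astype(float)
                terms = [(self.base_idx_fw, d_fw * open_site),
                         (self.base_idx_rc, d_rc * open_site)]
            elif ds_rule == "competitive":
                contrib = o_fw + o_rc - o_fw * o_rc
                terms = [(self.base_idx_fw, d_fw * (1.0 - o_rc)),
                         (self.base_idx_rc, d_rc * (1.0 - o_fw))]
            else:
                raise ValueError(f"unknown ds_rule {ds_rule!r}")
        probe_occ = np.bincount(self.probe_idx, weights=contrib,
                                minlength=self.n_probes)
        return probe_occ, terms


# ---------------------------------------------------------------------------
# scalar reference operations (readable, used directly on small inputs and as
# the public per-window API)


def window_energy(w: SubsequenceWindow, m: EnergyMatrix) -> float:
    """Total standard free energy of one window: dG0 + sum of matrix terms."""
    if w.encoded.shape[0] != m.length:
        raise ValueError("window length does not match matrix length")
    return float(m.dG0 + (w.encoded * m.ddG).sum())


def window_occupancy(energy: float, protein_conc: float = 1.0) -> float:
    """Langmuir occupancy c / (c + exp(energy)); strictly decreasing in energy."""
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    if protein_conc <= 0:
        raise ValueError("protein_conc must be positive")
    return float(protein_conc / (protein_conc + np.exp(min(energy, 700.0))))


def probe_occupancy(sequence: str, m: EnergyMatrix,
                    strandedness: str = "single", ds_rule: str = "clip") -> float:
    """Expected number of proteins bound to one probe (sum over windows)."""
    design = WindowDesign([sequence], m.length, strandedness)
    return float(design.occupancies(m, ds_rule)[0])


def occupancy_vector(ps, m: EnergyMatrix, ds_rule: str = "clip") -> np.ndarray:
    """Per-probe occupancies for a ProbeSet, in probe order."""
    design = WindowDesign(ps.sequences, m.length, ps.strandedness)
    return design.occupancies(m, ds_rule)
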