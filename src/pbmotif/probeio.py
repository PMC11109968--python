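"""Probe tables: reading/writing, signal transforms, padding, train/test splits.

Probe tables are plain-text TSV or CSV files (delimiter auto-detected, header
required) with one row per array spot carrying the probe sequence and its
normalized binding signal.  Signals are used as given; the only transform
offered is the opt-in squaring used when the deposited scores were
square-rooted upstream and a linear signal-occupancy relation is wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .thermo import SequenceError, encode_sequence

logger = logging.getLogger(__name__)


class ProbeTableError(ValueError):
    """Malformed probe table (missing columns, bad values)."""


@dataclass(frozen=True)
class Probe:
    """One array probe: identifier, DNA sequence and binding signal."""

    id: str
    sequence: str
    signal: float

    def __post_init__(self):
        encode_sequence(self.sequence)  # validates non-empty, ACGT-only
        if not np.isfinite(self.signal) or self.signal < 0:
            raise ValueError(
                f"probe {self.id!r}: signal must be finite and >= 0, "
                f"got {self.signal!r}")


@dataclass(frozen=True)
class ProbeSet:
    """An ordered collection of probes sharing a strandedness context."""

    probes: tuple
    strandedness: str = "single"
    name: str = ""

    def __post_init__(self):
        probes = tuple(self.probes)
        if not probes:
            raise ValueError("ProbeSet must contain at least one probe")
        if self.strandedness not in ("single", "double"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")
        ids = [p.id for p in probes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate probe ids in ProbeSet")
        object.__setattr__(self, "probes", probes)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.probes]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    @property
    def signals(self) -> np.ndarray:
        return np.array([p.signal for p in self.probes], dtype=float)

    def subset(self, indices) -> "ProbeSet":
        return replace(self, probes=tuple(self.probes[i] for i in indices))

    def with_signals(self, signals) -> "ProbeSet":
        signals = np.asarray(signals, dtype=float)
        if signals.shape != (len(self),):
            raise ValueError("signal vector length mismatch")
        return replace(self, probes=tuple(
            replace(p, signal=float(s)) for p, s in zip(self.probes, signals)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sequence": self.sequences,
            "signal": self.signals,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, seq_column: str = "sequence",
                       signal_column: str = "signal", id_column: str | None = "id",
                       strandedness: str = "single", name: str = "") -> "ProbeSet":
        for col in (seq_column, signal_column):
            if col not in df.columns:
                raise ProbeTableError(f"missing column {col!r}")
        if id_column is not None and id_column in df.columns:
            ids = df[id_column].astype(str).tolist()
        else:
            ids = [f"probe_{i}" for i in range(len(df))]
        probes = []
        for row_no, (pid, seq, sig) in enumerate(
                zip(ids, df[seq_column], df[signal_column])):
            if pd.isna(sig):
                raise ProbeTableError(f"row {row_no}: missing signal value")
            try:
                sig = float(sig)
            except (TypeError, ValueError):
                raise ProbeTableError(
                    f"row {row_no}: non-numeric signal {sig!r}") from None
            try:
                probes.append(Probe(pid, str(seq).strip().upper(), sig))
            except SequenceError as e:
                raise SequenceError(f"row {row_no}: {e}") from None
        return cls(tuple(probes), strandedness=strandedness, name=name)


def read_probe_table(path, seq_column: str = "sequence",
                     signal_column: str = "signal", id_column: str | None = "id",
                     strandedness: str = "single", name: str = "") -> ProbeSet:
    """Read a TSV/CSV probe table (header required, delimiter auto-detected)."""
    df = pd.read_csv(path, sep=None, engine="python")
    ps = ProbeSet.from_dataframe(df, seq_column, signal_column, id_column,
                                 strandedness=strandedness,
                                 name=name or str(path))
    logger.info("read %d probes from %s", len(ps), path)
    return ps


def write_probe_table(ps: ProbeSet, path, predicted_occupancy=None) -> None:
    """Write a TSV with columns id, sequence, signal (and optionally
    predicted_occupancy)."""
    df = ps.to_dataframe()
    if predicted_occupancy is not None:
        occ = np.asarray(predicted_occupancy, dtype=float)
        if occ.shape != (len(ps),):
            raise ValueError("predicted_occupancy length mismatch")
        df["predicted_occupancy"] = occ
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fasta_probes(fasta_path, signal_path, strandedness: str = "single",
                      name: str = "") -> ProbeSet:
    """Build a ProbeSet from a FASTA file plus a two-column id/signal table."""
    from Bio import SeqIO

    sig_df = pd.read_csv(signal_path, sep=None, engine="python")
    if sig_df.shape[1] < 2:
        raise ProbeTableError("signal table needs id and signal columns")
    id_col, sig_col = sig_df.columns[:2]
    signals = dict(zip(sig_df[id_col].astype(str), sig_df[sig_col]))
    probes = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in signals:
            raise ProbeTableError(f"no signal for FASTA record {rec.id!r}")
        probes.append(Probe(rec.id, str(rec.seq).upper(), float(signals[rec.id])))
    logger.info("read %d probes from %s", len(probes), fasta_path)
    return ProbeSet(tuple(probes), strandedness=strandedness,
                    name=name or str(fasta_path))


def square_signals(ps: ProbeSet) -> ProbeSet:
    """Square each signal (undoes an upstream square-root normalization so
    signal is proportional to occupancy); sequences untouched."""
    signals = ps.signals
    if (signals < 0).any():
        raise ValueError("negative signal cannot be squared meaningfully")
    return ps.with_signals(signals ** 2)


def pad_probes(ps: ProbeSet, pad: str, side: str = "3prime") -> ProbeSet:
    """Concatenate a constant sequence onto every probe (e.g. the invariant
    linker region of a custom array)."""
    if side not in ("5prime", "3prime"):
        raise ValueError(f"side must be '5prime' or '3prime', got {side!r}")
    if pad == "":
        return ps
    encode_sequence(pad)  # raises SequenceError on non-ACGT
    def padded(seq: str) -> str:
        return pad + seq if side == "5prime" else seq + pad
    return replace(ps, probes=tuple(
        replace(p, sequence=padded(p.sequence)) for p in ps.probes))


def split_train_test(ps: ProbeSet, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[ProbeSet, ProbeSet]:
    """Disjoint, exhaustive, seed-reproducible train/test partition."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(ps)
    if n < 2:
        raise ValueError("need at least 2 probes to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return ps.subset(train_idx), ps.subset(test_idx)
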