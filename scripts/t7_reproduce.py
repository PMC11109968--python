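#!/usr/bin/env python
"""Reanalyse the T7 primase custom-array binding data (optional).

Requires a local copy of the deposited probe table (3149 probes with
normalized, square-rooted binding scores; available from the Zenodo deposit
accompanying the original study).  Reproduces the headline analysis:

  * signals squared to linearize the signal-occupancy relation;
  * optional 3' padding with the constant-region hexamer GTCTTG;
  * 10x repeated 5-fold cross-validated motif-length scan (2-6 nt);
  * 200 random-restart fits at length 4 with dG0 in the fit and the
    max-occupancy penalty targeting 1 bound protein per probe;
  * motif extension / border growth / pruning to the final ~5-nt motif.

Usage:
    python scripts/t7_reproduce.py --probes t7_probes.tsv --outdir results/t7 \
        [--padding] [--seq-column sequence] [--signal-column signal]
"""

from __future__ import annotations

import argparse

from pbmotif.logo import motif_report
from pbmotif.probeio import pad_probes, read_probe_table, square_signals
from pbmotif.workflow import run_workflow, t7_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--probes", required=True,
                        help="TSV/CSV with the deposited probe table")
    parser.add_argument("--seq-column", default="sequence")
    parser.add_argument("--signal-column", default="signal")
    parser.add_argument("--padding", action="store_true",
                        help="append the constant-region hexamer GTCTTG 3'")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", required=True)
    args = parser.parse_args()

    ps = read_probe_table(args.probes, seq_column=args.seq_column,
                          signal_column=args.signal_column)
    print(f"parsed {len(ps)} probes")
    ps = square_signals(ps)
    if args.padding:
        ps = pad_probes(ps, "GTCTTG", "3prime")

    cfg = t7_config(seed=args.seed)
    report = run_workflow(ps, cfg, outdir=args.outdir)

    rep = motif_report(report.final.matrix)
    print(report.final.summary())
    print("\nmodel history:")
    print(report.history.to_string(index=False))
    print("\ncross-validated length scan:")
    print(report.length_table.to_string(index=False))
    print(f"\nfinal motif: {rep.consensus} ({rep.total_info:.2f} bit), "
          f"train r = {report.train_r:.3f}, test r = {report.test_r:.3f}, "
          f"mae = {report.final.mae:.3f}")


if __name__ == "__main__":
    main()
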