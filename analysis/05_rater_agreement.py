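#!/usr/bin/env python
"""Bland-Altman agreement between the automated and manual TW3 ratings.

Pairs the two TW3 rating columns of the simulated cohort, computes the
bias and rms deviation per sex over the conventional mid-rating ranges
(2.5-16 y boys, 2.5-14.5 y girls), and writes the Bland-Altman scatter
with its running-average curve.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import bonescale as bs
from bonescale import Sex

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort.csv")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    parser.add_argument("--figdir", type=Path, default=ROOT / "scratch" / "figures")
    args = parser.parse_args()

    cohort = bs.read_cohort(args.cohort)
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.figdir.mkdir(parents=True, exist_ok=True)

    summaries = {}
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, (sex, mid_hi) in zip(axes, ((Sex.MALE, 16.0), (Sex.FEMALE, 14.5))):
        pairs = bs.pair_ratings(cohort.filter(sex))
        summary = bs.bias_rms(pairs, 2.5, mid_hi)
        grid, means = bs.running_average(pairs)
        summaries[sex.value] = {
            "bias": round(summary.bias, 3),
            "rms": round(summary.rms, 3),
            "n": summary.n,
            "mid_range": list(summary.range),
        }
        print(f"{sex.value}: bias {summary.bias:+.2f} y, rms {summary.rms:.2f} y "
              f"over TW3mid {summary.range[0]:g}-{summary.range[1]:g} y (n={summary.n})")
        ax.plot([p.mid for p in pairs], [p.diff for p in pairs], ".", ms=2, alpha=0.3)
        ax.plot(grid, means, "k-", lw=1.5)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(sex.value)
        ax.set_xlabel("TW3mid (y)")
    axes[0].set_ylabel("automated $-$ manual TW3 (y)")
    fig.tight_layout()
    fig.savefig(args.figdir / "bland_altman.png", dpi=120)

    out = args.outdir / "agreement_summary.json"
    out.write_text(json.dumps(summaries, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
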