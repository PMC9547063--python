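"""Summary figures from the dilation experiment tables.

Reads the CSV outputs of 03_dilation_experiment.py and draws: relative
flow changes vs distance to the dilation centre (increases/decreases
separated), and affected-set flow SD per scenario against the expected
baseline heterogeneity levels.  Requires matplotlib.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    src = ROOT / "dilation"
    if not (src / "heterogeneity.csv").exists():
        sys.exit("run 03_dilation_experiment.py first")
    out = ROOT / "figures"
    out.mkdir(parents=True, exist_ok=True)

    prof = pd.read_csv(src / "distance_profiles.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, inc in zip(axes, (0.6, 1.1, 1.6)):
        sub = prof[prof.increment_um == inc]
        for direction, color in (("increase", "tab:red"), ("decrease", "tab:blue")):
            d = sub[sub.direction == direction]
            mids = (d.bin_lo_um + d.bin_hi_um) / 2
            ax.errorbar(
                mids, 100 * d["median"],
                yerr=[100 * (d["median"] - d.q1), 100 * (d.q3 - d["median"])],
                fmt="o", ms=4, color=color, label=direction,
            )
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"dilation +{inc} µm")
        ax.set_xlabel("distance to centre (µm)")
    axes[0].set_ylabel("relative flow change (%)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "distance_profile.png", dpi=150)

    het = pd.read_csv(src / "heterogeneity.csv")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for case, grp in het.groupby("case"):
        grp = grp.sort_values("increment_um")
        ax.plot(grp.increment_um.astype(float), grp.affected_flow_sd, "o-", label=case)
    ref = het.drop_duplicates("case")
    ax.axhline(ref.reference_median.mean(), ls="--", color="k", lw=1,
               label="baseline heterogeneity (median)")
    ax.axhline(ref.reference_q75.mean(), ls=":", color="k", lw=1, label="0.75 quantile")
    ax.set_xlabel("dilation increment (µm)")
    ax.set_ylabel("SD of affected-set flow (µm³/ms)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "heterogeneity.png", dpi=150)
    print("wrote figures under", out)


if __name__ == "__main__":
    main()
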