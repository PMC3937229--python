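#!/usr/bin/env python
"""Saturation analysis of the simulated screen: pseudo-kernel (+/- 7.5 kb)
coverage of CIS-member sites as a function of sample count, against a
random-placement control.  A driver-exhausted design (all drivers carried
by the first 15 tumours) shows the plateau signature.

Writes results/saturation.tsv and a quartile-band figure under scratch/.
"""

from pathlib import Path

import pandas as pd

from cis_select.cis_detection import GkcConfig
from cis_select.core import mm9_like_genome
from cis_select.evaluation import saturation_signature

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    genome = mm9_like_genome()
    config = GkcConfig(seed=0)
    sig = saturation_signature(genome, config, None, cohort_seed=3, curve_seed=11)
    real, ctrl = sig["real_curve"], sig["control_curve"]
    both = pd.concat([
        real.table.assign(label="real"), ctrl.table.assign(label="random_control"),
    ])
    both.to_csv(OUT / "saturation.tsv", sep="\t", index=False)
    print(f"{sig['n_cis']} CISs, {sig['n_member_sites']} member sites")
    print(f"marginal coverage gain at n=20: real {sig['real_gain']/1e3:.0f} kb vs "
          f"control {sig['control_gain']/1e3:.0f} kb (ratio {sig['gain_ratio']:.3f})")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for curve, color in ((real, "tab:blue"), (ctrl, "tab:orange")):
            t = curve.table
            ax.fill_between(t["n"], t["q25"] / 1e6, t["q75"] / 1e6, alpha=0.3, color=color)
            ax.plot(t["n"], t["median"] / 1e6, color=color, label=curve.label)
        ax.set_xlabel("number of samples")
        ax.set_ylabel("pseudo-kernel coverage (Mb)")
        ax.legend()
        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig.savefig(scratch / "saturation.png", dpi=120, bbox_inches="tight")
        print(f"figure: {scratch/'saturation.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
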