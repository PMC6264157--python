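#!/usr/bin/env python
"""Joint distributions of HAMP parameters against the architecture ratio.

Reads the descriptor table from 02, builds joint densities of each HAMP
parameter (Piston C2, Rotation N1, Average Tilt) against the
theta_HAD/theta_HA*D ratio, marks their local maxima, and reports the
maxima trend (Spearman sign) per pair.

Writes results/maps/<pair>.csv density grids and
results/correlation_report.json.
"""

from pathlib import Path

import pandas as pd

from hampkin.stats_maps import correlation_report, joint_distribution, write_report

ROOT = Path(__file__).resolve().parent.parent
MAPS = ROOT / "results" / "maps"

PARAMETERS = ["piston_C2", "rotation_N1", "tilt"]


def main() -> None:
    MAPS.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(ROOT / "results" / "descriptors.csv")
    report = correlation_report(df, ratio_column="ratio",
                                parameters=PARAMETERS, resolution=20)
    write_report(report, ROOT / "results" / "correlation_report.json")
    for name in PARAMETERS:
        dist = joint_distribution(df[name].to_numpy(), df["ratio"].to_numpy(),
                                  resolution=20)
        dist.to_csv(MAPS / f"{name}_vs_ratio.csv")
        pair = report["pairs"][name]
        print(f"{name} vs ratio: {pair['n_maxima']} maxima, "
              f"trend sign {pair['trend_sign']} "
              f"(rho {pair['spearman_rho']:.2f})")


if __name__ == "__main__":
    main()
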