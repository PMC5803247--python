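"""Differential testing of promoter / early / late gene-body regions.

Counts raw reads in the three fixed regions for genes > 800 nt, tests
treated vs untreated with the spike-in size factors, applies BH
correction, and classifies each gene-region as up/down/ns at adjusted
p < 0.01.
"""

import argparse

from common import make_config
from polwave import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    out = pipeline.run("diff", make_config(args.seed))
    res = out["results"]
    for region in ("promoter", "early", "late"):
        sub = res.xs(region, level="region")["call"].value_counts()
        print(f"{region:9s} up={sub.get('up', 0):3d} down={sub.get('down', 0):3d} "
              f"ns={sub.get('ns', 0):3d}")


if __name__ == "__main__":
    main()
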