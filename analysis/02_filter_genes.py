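"""Re-annotate TSSs from PRO-cap and filter genes for the analysis set.

Applies the three gates in order -- observed TSS (PRO-cap argmax with >4
normalized reads over background), Poisson activity against intergenic
background, and the upstream read-through comparison -- and reports how
many genes survive each.
"""

import argparse

from common import make_config
from polwave import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    out = pipeline.run("filter", make_config(args.seed))
    print(f"input genes:        {out['n_input']}")
    print(f"with observed TSS:  {out['n_observed_tss']}")
    print(f"active (p < 0.01):  {out['n_active']}")
    print(f"read-through clean: {out['n_readthrough_pass']}")
    print(f"final analysis set: {out['n_final']}")


if __name__ == "__main__":
    main()
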