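"""Generate the synthetic inhibition time course.

Builds the default study conditions -- 40 non-overlapping genes of 6-8 kb
on a two-chromosome toy genome, slow/fast Pol II populations at 400 and
1200 bp/min splitting at a 500 bp checkpoint, Poisson read noise, two
replicate libraries per condition over {0, 0.5, 1, 2.5, 5} min -- and
writes bedGraph tracks, the gene annotation, sample sheet, and the
ground-truth wave positions under results/data/.
"""

import argparse

from common import make_config
from polwave import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    config = make_config(args.seed)
    fixture = pipeline.run("simulate", config)
    genes = fixture["genes"]
    print(f"wrote {len(genes)} genes "
          f"({min(g.length for g in genes)}-{max(g.length for g in genes)} bp) "
          f"and {len(fixture['tracks'])} libraries to {config.data_dir}")


if __name__ == "__main__":
    main()
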