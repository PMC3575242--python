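#!/usr/bin/env python
"""In-silico PCR-RFLP screen of a synthetic 41-isolate panel: amplify each
clone with the element/28S primer pair, digest with the DraI + BspHI +
BstEII panel, code the three diagnostic cuts as haplotypes 1-8, and
summarize haplotypes per isolate.  A second pass injects PCR chimeras to
show how template switching inflates apparent haplotype diversity (the
wet-lab control ran longer elongation to suppress them).

Writes the haplotype frequency table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pokeyrec import evaluation as ev


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    clean = ev.rflp_screen_summary(seed=args.seed, n_isolates=41)
    chim = ev.rflp_screen_summary(seed=args.seed, n_isolates=41, chimera_rate=0.10)

    print("clean screen:   mean {mean:.2f} haplotypes/isolate, sd {sd:.2f}, "
          "max {max}".format(**clean))
    print("10% chimeras:   mean {mean:.2f} haplotypes/isolate, sd {sd:.2f}, "
          "max {max}".format(**chim))
    print("chimeric amplification inflates apparent haplotype diversity by "
          f"{chim['mean'] - clean['mean']:+.2f} haplotypes per isolate")

    pd.DataFrame([
        {"condition": "clean", **clean},
        {"condition": "chimera_rate_0.10", **chim},
    ]).to_csv(args.out / "rflp_screen.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
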