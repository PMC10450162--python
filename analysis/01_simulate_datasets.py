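#!/usr/bin/env python
"""Generate the synthetic study datasets.

Three two-condition datasets under the default study conditions (1500 genes,
every gene with an antisense partner, 6v6 replicates, NB dispersion 0.01,
deep counts) that differ only in the planted correlation of true sense and
antisense log2 fold-changes: rho = 0.9 (strong coupling), 0.5 (moderate),
and 0.0 (null).  Bundles are written under scratch/datasets/ (they are
regenerated on demand and are byte-identical per seed).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from antisense_pairs.synthetic import SimConfig, simulate_dataset

RHOS = (0.9, 0.5, 0.0)
SEED = 0
OUT = Path(__file__).resolve().parents[1] / "scratch" / "datasets"


def main() -> None:
    for rho in RHOS:
        cfg = SimConfig(rho=rho, seed=SEED)
        out = OUT / f"rho{rho:g}"
        manifest = simulate_dataset(cfg, out)
        print(f"rho={rho:g}: {manifest['n_planted_pairs']} planted pairs -> {out}")


if __name__ == "__main__":
    main()
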