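#!/usr/bin/env python
"""Generate the synthetic study world and write every pipeline input.

Produces TSV cross-link tables, per-replicate elution matrices, mmCIF
structures, a variant table, and the ground-truth JSON sidecar under
results/synthetic_inputs/.
"""

import json
from pathlib import Path

from endonet import synthetic

SEED = 1
OUT = Path("results/synthetic_inputs")


def main() -> None:
    world = synthetic.make_world(seed=SEED)
    paths = synthetic.write_world(world, OUT)
    n_endo = len(world.endosomal)
    print(f"world: {len(world.proteins)} proteins ({n_endo} endosomal), "
          f"{len(world.complexes)} complexes, "
          f"{len(world.structures)} structures")
    print(json.dumps(paths, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
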