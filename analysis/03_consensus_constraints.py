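#!/usr/bin/env python
"""Extract consensus interatomic distances from the hairpin ensemble,
weight them with the RAPDF table, and compile the three cutoff-limited
constraint sets (12 / 16 / 20 A).  Requires 01 and 02 to have run.
"""

from pathlib import Path

import numpy as np

from consfold import (
    RAPDFTable,
    attach_rapdf_weights,
    compile_constraint_sets,
    extract_consensus,
    read_ensemble,
    read_pdb,
)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "constraints"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ens = read_ensemble(BASE / "inputs" / "hairpin_ensemble.pdb")
    native = read_pdb(BASE / "inputs" / "hairpin_native.pdb")
    table = RAPDFTable.read(BASE / "scoring" / "rapdf_table.tsv")

    cons = extract_consensus(ens, window=0.5, min_support=4)
    print(f"{len(cons)} consensus distances "
          f"(window 0.5 A, quorum 4 of {len(ens)})")

    idx = native.atom_index()
    coords = native.coords()
    errors = [abs(c.distance - float(np.linalg.norm(
        coords[idx[c.atom_i]] - coords[idx[c.atom_j]]))) for c in cons]
    print(f"mean |consensus - native| distance error: "
          f"{np.mean(errors):.3f} A")

    weighted = attach_rapdf_weights(cons, table, ensemble_size=len(ens),
                                    sequence=ens.sequence)
    for cset in compile_constraint_sets(weighted, source="hairpin_ensemble"):
        path = OUT / f"constraints_{cset.cutoff:g}A.tsv"
        cset.write(path)
        print(f"cutoff {cset.cutoff:g} A: {len(cset)} constraints "
              f"(one best atom pair per residue pair) -> {path.name}")


if __name__ == "__main__":
    main()
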