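#!/usr/bin/env python
"""Generate the synthetic SP/SPH family used by the downstream analyses.

Builds a 221-gene family (120 SP / 101 SPH; 38 trypsins, 8
chymotrypsins; 13 clip-bearing genes with 14 clip domains), its scaffold
layout and its stage/tissue RPKM matrices, and writes the bundle plus
the ground-truth manifest under results/fixtures/.
"""

from pathlib import Path

from spfam.synth import FamilySpec, write_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    spec = FamilySpec(seed=11)
    manifest = write_fixtures(OUT, spec)
    comp = manifest.composition()
    print(f"wrote fixture bundle to {OUT}")
    print(
        f"family: {comp['n_genes']} genes = {comp['n_sp']} SP + "
        f"{comp['n_sph']} SPH; {comp['n_trypsin']} trypsins, "
        f"{comp['n_chymotrypsin']} chymotrypsins; "
        f"{comp['n_clip_genes']} clip-bearing genes with "
        f"{comp['n_clip_domains']} clip domains"
    )


if __name__ == "__main__":
    main()
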