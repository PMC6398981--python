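#!/usr/bin/env python
"""Download the deposited DraNramp coordinate files used by the real-data tests.

Requires network access. Fetches PDB entries 6D9W, 6C3I, 6BU5 and 6D91 (plus
the ScaNramp/EcoNramp comparators 5M95 and 5KTE) into data/structures/.

The 6878-sequence family alignment is supplementary material of the source
publication (eLife 10.7554/eLife.41124, "Figure 2—source data 1") and must be
downloaded manually from the journal; save it as data/alignment/nramp_msa.fasta.

Usage:
    python scripts/fetch_data.py
"""

from pathlib import Path
from urllib.request import urlretrieve

ACCESSIONS = ["6D9W", "6C3I", "6BU5", "6D91", "5M95", "5KTE"]
BASE = "https://files.rcsb.org/download/{}.cif"

def main() -> None:
    dest = Path(__file__).resolve().parents[1] / "data" / "structures"
    dest.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        target = dest / f"{acc}.cif"
        if target.exists():
            print(f"{target} already present")
            continue
        print(f"fetching {acc} ...")
        urlretrieve(BASE.format(acc), target)
    print("done. Remember to place the family alignment at data/alignment/nramp_msa.fasta")


if __name__ == "__main__":
    main()
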