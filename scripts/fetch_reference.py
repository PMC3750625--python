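#!/usr/bin/env python
"""Download the Mo-MLV integrase NTD crystal structure (PDB entry 3NNQ)
into data/reference/3nnq.pdb.

The coordinate file is not redistributed with the package; the
structure-dependent checks in the test suite need it and will report its
absence otherwise.  Requires network access to the RCSB PDB.
"""

import os
import sys
import urllib.request

URL = "https://files.rcsb.org/download/3NNQ.pdb"


def main() -> int:
    root = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
    dest = os.path.join(root, "data", "reference", "3nnq.pdb")
    if os.path.exists(dest):
        print(f"already present: {dest}")
        return 0
    os.makedirs(os.path.dirname(dest), exist_ok=True)
    print(f"fetching {URL} ...")
    with urllib.request.urlopen(URL, timeout=60) as resp:
        data = resp.read()
    with open(dest, "wb") as fh:
        fh.write(data)
    print(f"wrote {dest} ({len(data)} bytes)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
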