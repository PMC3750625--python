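# Reference coordinates

This directory holds third-party crystallographic coordinates that are
not redistributed with the package.

Expected file:

- `3nnq.pdb` — the Mo-MLV integrase N-terminal domain crystal structure
  (PDB entry 3NNQ). Fetch it with

      python scripts/fetch_reference.py

  (requires network access), or place the file here manually. The
  structure-dependent tests in `tests/test_acceptance.py` and the
  `analysis/02_monomer_validation.py` driver use it; everything else in
  the package runs without it.
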