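# Experimental coordinate files (not shipped)

The published-results tests in `tests/test_acceptance.py` reproduce LIP
maps on five experimentally solved structures. Third-party coordinates
are not distributed with this package; to run those tests, place the
files here as lowercase `<pdbid>.pdb`:

    1ftg.pdb  1hrc.pdb  1hml.pdb  2c3z.pdb  1a2p.pdb

(e.g. from https://files.rcsb.org/download/1FTG.pdb). The baseline test
additionally looks for a reference set of solved structures under
`table_s1/*.pdb`. Without these files the corresponding tests report a
failure with an explanatory message; all other tests are self-contained.
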