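# data/

Holding area for deposited third-party inputs used by acceptance targets
t7-t11. Nothing here is bundled with the repository; populate it with

    python scripts/fetch_deposited_data.py
    python scripts/make_residue_maps.py

which download the PDB entries (6F8H, 6F1X, 6F8S, 3TRB, 4MCX) into
`structures/`, the SASBDB curve SASDE48 into `saxs/`, and write the
alignment-derived residue maps into `structures/maps/`.
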