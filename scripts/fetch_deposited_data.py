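#!/usr/bin/env python
"""Fetch the deposited third-party data needed by acceptance targets t7-t11.

Downloads (plain-text files, a few hundred kB each):
  - PDB entries 6F8H, 6F1X, 6F8S, 3TRB, 4MCX  ->  data/structures/
  - SASBDB entry SASDE48 scattering curve     ->  data/saxs/

Requires network access; run once, then scripts/make_residue_maps.py to
build the residue-correspondence fixtures used by t9 and t11.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parents[1]

PDB_IDS = ("6F8H", "6F1X", "6F8S", "3TRB", "4MCX")
PDB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
SASBDB_URLS = (
    "https://www.sasbdb.org/media/intensities_files/SASDE48.dat",
    "https://www.sasbdb.org/rest-api/entry/intensities/SASDE48.dat",
)


def fetch(url: str, dest: Path) -> bool:
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            data = resp.read()
    except Exception as exc:  # noqa: BLE001
        print(f"  failed: {url} ({exc})", file=sys.stderr)
        return False
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    print(f"  wrote {dest} ({len(data)} bytes)")
    return True


def main() -> int:
    ok = True
    struct_dir = REPO_ROOT / "data" / "structures"
    for pdb_id in PDB_IDS:
        dest = struct_dir / f"{pdb_id}.pdb"
        if dest.exists():
            print(f"  {dest} already present")
            continue
        ok &= fetch(PDB_URL.format(pdb_id=pdb_id), dest)

    saxs_dest = REPO_ROOT / "data" / "saxs" / "SASDE48.dat"
    if not saxs_dest.exists():
        got = any(fetch(url, saxs_dest) for url in SASBDB_URLS)
        if got:
            _normalize_sasbdb(saxs_dest)
        ok &= got
    return 0 if ok else 1


def _normalize_sasbdb(path: Path) -> None:
    """SASBDB curves sometimes carry header lines; comment them out."""
    lines = []
    for raw in path.read_text().splitlines():
        fields = raw.split()
        numeric = len(fields) in (2, 3)
        if numeric:
            try:
                [float(x) for x in fields]
            except ValueError:
                numeric = False
        lines.append(raw if numeric else f"# {raw}")
    path.write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    sys.exit(main())
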