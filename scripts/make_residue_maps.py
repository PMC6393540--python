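#!/usr/bin/env python
"""Build the residue-correspondence fixtures for targets t9 and t11.

Aligns the antitoxin chain of 6F8H against the HigA homolog 3TRB, and the
antitoxin/toxin chains of 6F8S against 4MCX, by global sequence alignment
of the CA-residue sequences (Needleman-Wunsch, BLOSUM62).  Writes TSV maps
(column 1: residue number in the first structure; column 2: equivalent
residue number in the homolog) plus a chains.json with the chain choices,
so every downstream RMSD/rotation is deterministic.

Run after scripts/fetch_deposited_data.py.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB.Polypeptide import protein_letters_3to1

REPO_ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = REPO_ROOT / "data" / "structures"
MAPS_DIR = DATA_DIR / "maps"

sys.path.insert(0, str(REPO_ROOT / "src"))

from coopfold.structure_metrics import read_structure  # noqa: E402


def chain_sequence(model, chain: str) -> tuple[str, list[int]]:
    """One-letter sequence and residue numbers of a chain's CA trace."""
    seq, numbers = [], []
    for atom in model.atoms:
        if atom.chain == chain and atom.name == "CA":
            letter = protein_letters_3to1.get(atom.resname, "X")
            seq.append(letter)
            numbers.append(atom.resnum)
    return "".join(seq), numbers


def align_map(model_a, chain_a: str, model_b, chain_b: str) -> dict[int, int]:
    seq_a, num_a = chain_sequence(model_a, chain_a)
    seq_b, num_b = chain_sequence(model_b, chain_b)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    alignment = aligner.align(seq_a, seq_b)[0]
    mapping: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            mapping[num_a[a_start + offset]] = num_b[b_start + offset]
    return mapping


def protein_chains(model) -> list[str]:
    """Chains with >= 30 CA atoms, longest first."""
    counts: dict[str, int] = {}
    for atom in model.atoms:
        if atom.name == "CA":
            counts[atom.chain] = counts.get(atom.chain, 0) + 1
    return sorted((c for c, n in counts.items() if n >= 30),
                  key=lambda c: -counts[c])


def write_map(mapping: dict[int, int], path: Path, header: str) -> None:
    lines = [f"# {header}"]
    lines += [f"{a}\t{b}" for a, b in sorted(mapping.items())]
    path.write_text("\n".join(lines) + "\n")
    print(f"  wrote {path} ({len(mapping)} pairs)")


def main() -> int:
    MAPS_DIR.mkdir(parents=True, exist_ok=True)

    free = read_structure(DATA_DIR / "6F8H.pdb")
    higa = read_structure(DATA_DIR / "3TRB.pdb")
    chain_free = protein_chains(free)[0]
    chain_higa = protein_chains(higa)[0]
    write_map(
        align_map(free, chain_free, higa, chain_higa),
        MAPS_DIR / "6F8H_to_3TRB.tsv",
        f"6F8H chain {chain_free} -> 3TRB chain {chain_higa} (BLOSUM62 global)",
    )

    ta = read_structure(DATA_DIR / "6F8S.pdb")
    higba = read_structure(DATA_DIR / "4MCX.pdb")
    # antitoxin chains are the longer protein chains in both complexes;
    # the toxin is the partner chain.  Verified against the deposited
    # headers when the data are fetched.
    ta_chains = protein_chains(ta)
    hig_chains = protein_chains(higba)
    ta_anti, ta_tox = ta_chains[0], ta_chains[-1]
    hig_anti, hig_tox = hig_chains[0], hig_chains[-1]
    write_map(
        align_map(ta, ta_anti, higba, hig_anti),
        MAPS_DIR / "6F8S_antitoxin_to_4MCX.tsv",
        f"6F8S chain {ta_anti} -> 4MCX chain {hig_anti}",
    )
    write_map(
        align_map(ta, ta_tox, higba, hig_tox),
        MAPS_DIR / "6F8S_toxin_to_4MCX.tsv",
        f"6F8S chain {ta_tox} -> 4MCX chain {hig_tox}",
    )
    chains = {
        "6F8S_antitoxin": ta_anti,
        "6F8S_toxin": ta_tox,
        "4MCX_antitoxin": hig_anti,
        "4MCX_toxin": hig_tox,
    }
    (MAPS_DIR / "chains.json").write_text(json.dumps(chains, indent=2) + "\n")
    print(f"  wrote {MAPS_DIR / 'chains.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
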