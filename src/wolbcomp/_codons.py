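"""Codon-table helpers shared by the simulator and the divergence engine.

Everything is precomputed once from NCBI translation table 11 (bacterial);
start-codon alternatives are ignored (ATG-only starts by construction in the
simulator, and Ka/Ks never looks at start status).
"""

from __future__ import annotations

from Bio.Data import CodonTable

NT = "ACGT"

_T11 = CodonTable.unambiguous_dna_by_id[11]

CODON_TO_AA: dict[str, str] = dict(_T11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_T11.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_cds(seq: str) -> str:
    """Translate a CDS codon-by-codon; stops become '*'. Length must be %3."""
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        c = seq[i : i + 3]
        out.append("*" if c in STOP_CODONS else CODON_TO_AA.get(c, "X"))
    return "".join(out)


def _neighbors(codon: str):
    for pos in range(3):
        for alt in NT:
            if alt != codon[pos]:
                yield pos, codon[:pos] + alt + codon[pos + 1 :]


# For every sense codon: single-nucleotide neighbors split by effect.
SYN_NEIGHBORS: dict[str, tuple[tuple[int, str], ...]] = {}
NONSYN_NEIGHBORS: dict[str, tuple[tuple[int, str], ...]] = {}  # sense only
STOP_NEIGHBORS: dict[str, tuple[tuple[int, str], ...]] = {}

for _c in SENSE_CODONS:
    syn, non, stp = [], [], []
    for _pos, _alt in _neighbors(_c):
        if _alt in STOP_CODONS:
            stp.append((_pos, _alt))
        elif CODON_TO_AA[_alt] == CODON_TO_AA[_c]:
            syn.append((_pos, _alt))
        else:
            non.append((_pos, _alt))
    SYN_NEIGHBORS[_c] = tuple(syn)
    NONSYN_NEIGHBORS[_c] = tuple(non)
    STOP_NEIGHBORS[_c] = tuple(stp)
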