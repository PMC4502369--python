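"""HGVS coding/protein notation: parsing, formatting, codon arithmetic.

Protein changes use three-letter amino-acid codes with ``*`` for stop,
``p.Gln102*`` for a gained stop, and ``p.*111Leuext*22`` for a lost stop
where translation reads through the 3' UTR and terminates at the 22nd
in-frame downstream codon (``ext*?`` when no in-frame stop exists before
the UTR runs out).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(standard_dna_table.forward_table)  # 1-letter, stops absent


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``*`` for stop."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"bad codon {codon!r}")
    return "*" if codon in STOP_CODONS else _CODON_TO_AA[codon]


def aa3(one_letter: str) -> str:
    """Three-letter amino-acid name, keeping ``*`` for stop."""
    return "*" if one_letter == "*" else seq3(one_letter)


def codon_index(cds_pos: int) -> tuple[int, int]:
    """(1-based codon number, 0-based offset within codon) of a CDS position.

    Inverse identity: ``3 * (codon - 1) + offset + 1 == cds_pos``.
    """
    if cds_pos < 1:
        raise ValueError("CDS positions are 1-based")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3


_HGVS_C = re.compile(r"c\.(\d+)\s*([ACGT])\s*>\s*([ACGT])")
_HGVS_P = re.compile(
    r"p\.(\*|[A-Z][a-z]{2})(\d+)(\*|=|[A-Z][a-z]{2})(?:ext\*(\d+|\?))?"
)


def format_hgvs_c(cds_pos: int, ref: str, alt: str) -> str:
    return f"c.{cds_pos}{ref.upper()}>{alt.upper()}"


def parse_hgvs_c(text: str) -> tuple[int, str, str]:
    """Parse ``c.304C>T`` (whitespace around ``>`` tolerated)."""
    m = _HGVS_C.search(text)
    if not m:
        raise ValueError(f"cannot parse HGVS coding change {text!r}")
    return int(m.group(1)), m.group(2), m.group(3)


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str  # three-letter or "*"
    codon: int
    alt_aa: str  # three-letter, "*" (stopgain) or "=" (synonymous)
    ext: int | str | None = None  # stop-loss extension: int, "?" or None


def parse_hgvs_p(text: str) -> ProteinChange:
    """Parse ``p.Gln102*`` / ``p.*111Leuext*22`` / ``p.*1566Leuext*?``."""
    m = _HGVS_P.search(text)
    if not m:
        raise ValueError(f"cannot parse HGVS protein change {text!r}")
    ext: int | str | None = m.group(4)
    if ext is not None and ext != "?":
        ext = int(ext)
    return ProteinChange(
        ref_aa=m.group(1), codon=int(m.group(2)), alt_aa=m.group(3), ext=ext
    )


def format_hgvs_p(
    ref_aa: str, codon: int, alt_aa: str, ext: int | str | None = None
) -> str:
    """Assemble a protein-change string from its parts (1-letter aa input)."""
    ref3, alt3 = aa3(ref_aa), aa3(alt_aa)
    if ref_aa == alt_aa:
        return f"p.{ref3}{codon}="
    if ref_aa == "*":
        suffix = "?" if ext in (None, "?") else str(ext)
        return f"p.*{codon}{alt3}ext*{suffix}"
    if alt_aa == "*":
        return f"p.{ref3}{codon}*"
    return f"p.{ref3}{codon}{alt3}"


# ----------------------------------------------------- toy CDS construction

_FILLER = "GCT"  # Ala: never a stop, keeps reading frames inert
_ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]


def _solve_codon(aa_three: str, offset: int, base: str, mutated_aa: str,
                 alt_base: str) -> str:
    """A codon encoding ``aa_three`` with ``base`` at ``offset`` such that
    substituting ``alt_base`` there encodes ``mutated_aa``."""
    for codon in _ALL_CODONS:
        if codon[offset] != base:
            continue
        if aa3(translate_codon(codon)) != aa_three:
            continue
        mutated = codon[:offset] + alt_base + codon[offset + 1 :]
        target = "=" if mutated_aa == "=" else mutated_aa
        got = aa3(translate_codon(mutated))
        if target == "=" and got == aa_three:
            return codon
        if got == target:
            return codon
    raise ValueError(
        f"no codon encodes {aa_three} with {base} at offset {offset} "
        f"mutating to {mutated_aa}"
    )


def build_context(hgvs_c: str, hgvs_p: str) -> tuple[str, str, int, str]:
    """Minimal (cds_seq, utr3_seq, cds_pos, alt_base) realizing an HGVS pair.

    Reconstructs a toy coding context consistent with a printed coding
    change and its protein-level consequence: the affected codon encodes
    the stated reference residue with the stated reference base at the
    computed within-codon offset, the CDS starts with ATG and ends with a
    stop, and for stop-loss changes the 3' UTR places the first in-frame
    stop exactly where the ``ext*N`` annotation demands (or nowhere, for
    ``ext*?``).
    """
    cds_pos, ref_base, alt_base = parse_hgvs_c(hgvs_c)
    change = parse_hgvs_p(hgvs_p)
    codon_no, offset = codon_index(cds_pos)
    if codon_no != change.codon:
        raise ValueError(
            f"coding position {cds_pos} lands in codon {codon_no}, "
            f"not {change.codon}"
        )
    affected = _solve_codon(change.ref_aa, offset, ref_base, change.alt_aa,
                            alt_base)
    if change.ref_aa == "*":
        # stop-loss: affected stop codon terminates the CDS
        codons = ["ATG"] + [_FILLER] * (codon_no - 2) + [affected]
        if change.ext == "?" or change.ext is None:
            utr3 = _FILLER * 12 + "GC"  # no in-frame stop anywhere
        else:
            utr3 = _FILLER * (int(change.ext) - 1) + "TAA" + "GCAT"
    else:
        codons = ["ATG"] + [_FILLER] * (codon_no - 2) + [affected]
        codons += [_FILLER, "TAA"]  # finish the frame with a real stop
        utr3 = _FILLER * 4
    if codon_no == 1:
        raise ValueError("cannot place the affected codon over the start codon")
    return "".join(codons), utr3, cds_pos, alt_base
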