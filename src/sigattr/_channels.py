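"""Canonical mutation-type channel label lists.

Labels follow the COSMIC site conventions: SBS96 as ``A[C>A]A``-style
trinucleotide contexts grouped by pyrimidine-centric substitution class,
DBS78 as ``AC>CA``-style doublet substitutions, ID83 as
``1:Del:C:0``-style indel categories.
"""

from __future__ import annotations

from itertools import product


def _sbs96_labels() -> list[str]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return [
        f"{five}[{sub}]{three}"
        for sub in subs
        for five, three in product(bases, bases)
    ]


# Reference doublet -> allowed alternate doublets (strand-collapsed classes).
_DBS_ALTS = {
    "AC": ["CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "AT": ["CA", "CC", "CG", "GA", "GC", "TA"],
    "CC": ["AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "CG": ["AT", "GC", "GT", "TA", "TC", "TT"],
    "CT": ["AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"],
    "GC": ["AA", "AG", "AT", "CA", "CG", "TA"],
    "TA": ["AT", "CG", "CT", "GC", "GG", "GT"],
    "TC": ["AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"],
    "TG": ["AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"],
    "TT": ["AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"],
}


def _dbs78_labels() -> list[str]:
    return [f"{ref}>{alt}" for ref, alts in _DBS_ALTS.items() for alt in alts]


def _id83_labels() -> list[str]:
    labels: list[str] = []
    # 1-bp deletions/insertions by repeat length of the deleted/inserted base
    for op in ("Del", "Ins"):
        for base in ("C", "T"):
            labels.extend(f"1:{op}:{base}:{n}" for n in range(6))
    # >=2-bp deletions in repeat regions
    for size in (2, 3, 4, 5):
        labels.extend(f"{size}:Del:R:{n}" for n in range(6))
    # >=2-bp insertions in repeat regions
    for size in (2, 3, 4, 5):
        labels.extend(f"{size}:Ins:R:{n}" for n in range(6))
    # deletions with microhomology
    labels.append("2:Del:M:1")
    labels.extend(f"3:Del:M:{n}" for n in (1, 2))
    labels.extend(f"4:Del:M:{n}" for n in (1, 2, 3))
    labels.extend(f"5:Del:M:{n}" for n in (1, 2, 3, 4, 5))
    return labels


SBS96_LABELS: tuple[str, ...] = tuple(_sbs96_labels())
DBS78_LABELS: tuple[str, ...] = tuple(_dbs78_labels())
ID83_LABELS: tuple[str, ...] = tuple(_id83_labels())

assert len(SBS96_LABELS) == 96
assert len(DBS78_LABELS) == 78
assert len(ID83_LABELS) == 83
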