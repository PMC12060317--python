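"""Sequence primitives: target sites, PAM classes, PAM scanning and tiling sgRNA design.

Coordinate conventions
----------------------
Protospacer positions are 1-based with position 1 at the PAM-distal end and
position 20 adjacent to the PAM, matching the axis convention of editing-window
plots.  Locus offsets are 0-based half-open on the sense (given) strand.

A :class:`TargetSite` always lives on the strand that carries the target
adenine: a C-to-T pathogenic variant (T on the given strand) is designed on the
antisense strand, because adenine base editors act on A only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

#: order in which candidate target positions are tried by the tiling designer
TILING_PRIORITY = (6, 5, 7, 4, 8, 3, 9, 2, 10, 11, 12)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: canonical PAM classes; NRN == NGN ∪ NAN, NCW == {NCA, NCT}, NTR == {NTA, NTG}
PAM_CLASS_PATTERNS = {
    "NRN": "NRN",
    "NYN": "NYN",
    "NGN": "NGN",
    "NAN": "NAN",
    "NCW": "NCW",
    "NTR": "NTR",
    "NGG": "NGG",
    "NAG": "NAG",
}


def _expand_iupac(pattern: str) -> frozenset[str]:
    sets = [_IUPAC[c] for c in pattern]
    out = set()

    def rec(prefix, rest):
        if not rest:
            out.add(prefix)
            return
        for c in rest[0]:
            rec(prefix + c, rest[1:])

    rec("", sets)
    return frozenset(out)


@dataclass(frozen=True)
class PamClass:
    """A named PAM class resolved to an explicit set of trinucleotides."""

    name: str
    trinucs: frozenset[str]

    @classmethod
    def from_name(cls, name: str) -> "PamClass":
        key = name.upper()
        if key not in PAM_CLASS_PATTERNS:
            raise ValueError(
                f"unknown PAM class {name!r}; known: {sorted(PAM_CLASS_PATTERNS)}"
            )
        return cls(key, _expand_iupac(PAM_CLASS_PATTERNS[key]))

    def matches(self, trinuc: str) -> bool:
        return trinuc.upper() in self.trinucs


def resolve_pam_classes(classes) -> list[PamClass]:
    """Accept PamClass objects or names (possibly comma-separated) and resolve."""
    out = []
    for c in classes:
        if isinstance(c, PamClass):
            out.append(c)
        else:
            for name in str(c).split(","):
                if name.strip():
                    out.append(PamClass.from_name(name.strip()))
    if not out:
        raise ValueError("no PAM classes given")
    return out


def validate_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate; degenerate IUPAC letters are rejected."""
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in DNA_ALPHABET:
            raise ValueError(f"non-ACGT character {c!r} in {what} at offset {i}")
    return s


@dataclass(frozen=True)
class TargetSite:
    """One sgRNA/target pair on the strand carrying the target adenine.

    ``pam_context`` holds the 4 nt immediately 3' of the protospacer (model
    input); the designer validates only its first 3 nt against the PAM class.
    ``flank3`` starts immediately 3' of the 3-nt PAM, so its first base equals
    ``pam_context[3]``.  ``frame_offset`` is the reading-frame phase of
    protospacer position 1 on the protospacer strand (0/1/2) or "noncoding".
    """

    site_id: str
    gene_id: str
    protospacer: str
    pam_context: str
    flank5: str = ""
    flank3: str = ""
    target_pos: int = 6
    strand: str = "+"
    frame_offset: object = "noncoding"

    def __post_init__(self):
        object.__setattr__(self, "protospacer", validate_dna(self.protospacer, "protospacer"))
        object.__setattr__(self, "pam_context", validate_dna(self.pam_context, "pam_context"))
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if len(self.pam_context) != 4:
            raise ValueError(f"pam_context must be 4 nt, got {len(self.pam_context)}")
        if not 1 <= self.target_pos <= 20:
            raise ValueError(f"target_pos out of protospacer: {self.target_pos}")
        if self.protospacer[self.target_pos - 1] != "A":
            raise ValueError(
                f"protospacer position {self.target_pos} is "
                f"{self.protospacer[self.target_pos - 1]!r}, expected 'A'"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.frame_offset != "noncoding" and self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0/1/2 or 'noncoding'")

    @property
    def pam3(self) -> str:
        """The 3-nt PAM validated at design time (positions 21-23)."""
        return self.pam_context[:3]

    @property
    def a_positions(self) -> tuple[int, ...]:
        """1-based protospacer positions carrying an adenine."""
        return tuple(i + 1 for i, c in enumerate(self.protospacer) if c == "A")

    def context_motif(self) -> str:
        """Trinucleotide motif 5'N-A-3'N around the target adenine."""
        p = self.target_pos
        left = self.protospacer[p - 2] if p >= 2 else (self.flank5[-1] if self.flank5 else "N")
        right = self.protospacer[p] if p <= 19 else self.pam_context[0]
        return left + "A" + right


def scan_pams(locus_seq: str, classes) -> list[tuple[int, str, str, str]]:
    """Scan both strands of ``locus_seq`` for PAM trinucleotides.

    Returns ``(offset, strand, trinucleotide, class_name)`` tuples.  The offset
    is the sense-strand (0-based) coordinate of the leftmost base of the
    trinucleotide's footprint; the trinucleotide itself is reported in the
    orientation of the hit strand.
    """
    seq = validate_dna(locus_seq, "locus_seq")
    if len(seq) < 3:
        raise ValueError(f"sequence too short to host a PAM trinucleotide: {len(seq)} nt")
    classes = resolve_pam_classes(classes)
    hits = []
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - 2):
        tri_fwd = seq[i:i + 3]
        tri_rev = rc[i:i + 3]
        for cls in classes:
            if cls.matches(tri_fwd):
                hits.append((i, "+", tri_fwd, cls.name))
            if cls.matches(tri_rev):
                hits.append((n - 3 - i, "-", tri_rev, cls.name))
    hits.sort()
    return hits


def design_tiling_sgrnas(
    locus_seq: str,
    variant_offset: int,
    classes,
    max_guides: int = 6,
    *,
    site_id_prefix: str = "site",
    gene_id: str = "gene",
    variant_frame: object = "noncoding",
) -> list[TargetSite]:
    """Design up to ``max_guides`` tiling sgRNAs for one pathogenic adenine.

    Candidate protospacers place the target A at positions 6, 5, 7, 4, 8, 3,
    9, 2, 10, 11, 12 (in that priority order); a candidate is emitted only if
    a PAM of an allowed class sits immediately 3' of it.  If the given strand
    carries T at ``variant_offset``, design switches to the antisense strand.

    ``variant_frame`` is the codon phase of the variant base on the designed
    strand (0/1/2) or "noncoding"; each emitted site stores the derived phase
    of its protospacer position 1.
    """
    seq = validate_dna(locus_seq, "locus_seq")
    classes = resolve_pam_classes(classes)
    if not 0 <= variant_offset < len(seq):
        raise ValueError(f"variant_offset {variant_offset} outside locus of {len(seq)} nt")
    base = seq[variant_offset]
    if base == "A":
        work, v, strand = seq, variant_offset, "+"
    elif base == "T":
        work = reverse_complement(seq)
        v, strand = len(seq) - 1 - variant_offset, "-"
    else:
        raise ValueError(
            f"variant base {base!r} at offset {variant_offset} is not an adenine "
            "on either strand"
        )

    sites = []
    for t in TILING_PRIORITY:
        if len(sites) >= max_guides:
            break
        start = v - (t - 1)
        if start < 0 or start + 24 > len(work):
            continue
        pam3 = work[start + 20:start + 23]
        if not any(cls.matches(pam3) for cls in classes):
            continue
        if variant_frame == "noncoding":
            frame = "noncoding"
        else:
            frame = (int(variant_frame) - (t - 1)) % 3
        sites.append(TargetSite(
            site_id=f"{site_id_prefix}_p{t:02d}",
            gene_id=gene_id,
            protospacer=work[start:start + 20],
            pam_context=work[start + 20:start + 24],
            flank5=work[:start],
            flank3=work[start + 23:],
            target_pos=t,
            strand=strand,
            frame_offset=frame,
        ))
    if 0 < len(sites) < 5:
        logger.info("locus %s: only %d feasible guides (<5)", site_id_prefix, len(sites))
    return sites


def build_oligo(site: TargetSite, scaffold_seq: str, flank_len: int = 30) -> str:
    """Assemble the self-targeting oligo: spacer + scaffold + target cassette.

    The spacer is the protospacer with position 1 substituted by G when it is
    not already G (U6 transcription start); the target cassette keeps the
    genuine genomic base.  The cassette is ``flank5[-flank_len:]`` +
    protospacer + 3-nt PAM + ``flank3[:flank_len]``.
    """
    scaffold = validate_dna(scaffold_seq, "scaffold_seq")
    if len(site.flank5) < flank_len or len(site.flank3) < flank_len:
        raise ValueError(
            f"site {site.site_id}: need {flank_len} nt flanks, have "
            f"5'={len(site.flank5)} and 3'={len(site.flank3)}"
        )
    spacer = site.protospacer if site.protospacer[0] == "G" else "G" + site.protospacer[1:]
    cassette = site.flank5[-flank_len:] + site.protospacer + site.pam3 + site.flank3[:flank_len]
    return spacer + scaffold + cassette


def parse_oligo(oligo: str, scaffold_seq: str, flank_len: int = 30):
    """Invert :func:`build_oligo`: recover (spacer, protospacer, pam, (flank5, flank3)).

    The scaffold must occur exactly once; the protospacer is located by the
    19-nt spacer suffix (position 1 may be G-substituted in the spacer).
    Shorter-than-expected flanks are tolerated with a warning.
    """
    oligo = validate_dna(oligo, "oligo")
    scaffold = validate_dna(scaffold_seq, "scaffold_seq")
    first = oligo.find(scaffold)
    if first == -1:
        raise ValueError("scaffold not found in oligo")
    if oligo.find(scaffold, first + 1) != -1:
        raise ValueError("scaffold occurs more than once in oligo; cannot anchor")
    spacer = oligo[:first]
    cassette = oligo[first + len(scaffold):]
    if len(spacer) != 20:
        raise ValueError(f"spacer upstream of scaffold is {len(spacer)} nt, expected 20")
    j = cassette.find(spacer[1:])
    if j < 1:
        raise ValueError("protospacer matching the spacer not found in target cassette")
    protospacer = cassette[j - 1:j + 19]
    flank5 = cassette[:j - 1]
    pam = cassette[j + 19:j + 22]
    flank3 = cassette[j + 22:]
    if len(flank5) < flank_len or len(flank3) < flank_len:
        logger.warning(
            "truncated cassette flanks: 5'=%d nt, 3'=%d nt (expected %d)",
            len(flank5), len(flank3), flank_len,
        )
    return spacer, protospacer, pam, (flank5, flank3)


# SpCas9 optimized scaffold used for oligo assembly (default for CLI round-trips)
DEFAULT_SCAFFOLD = (
    "GTTTAAGAGCTATGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGT"
    "GGCACCGAGTCGGTGC"
)

LIBRARY_COLUMNS = [
    "site_id", "gene_id", "protospacer", "pam_context", "flank5", "flank3",
    "target_pos", "strand", "frame_offset",
]


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, c) for c in LIBRARY_COLUMNS} for s in sites])


def frame_to_sites(df: pd.DataFrame) -> list[TargetSite]:
    sites = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in LIBRARY_COLUMNS}
        fo = d["frame_offset"]
        d["frame_offset"] = "noncoding" if str(fo) == "noncoding" else int(fo)
        d["target_pos"] = int(d["target_pos"])
        d["flank5"] = "" if pd.isna(d["flank5"]) else str(d["flank5"])
        d["flank3"] = "" if pd.isna(d["flank3"]) else str(d["flank3"])
        sites.append(TargetSite(**d))
    return sites


def write_library_tsv(sites, path, oligos: dict | None = None) -> None:
    df = sites_to_frame(sites)
    if oligos:
        df["oligo"] = [oligos.get(s.site_id, "") for s in sites]
    with open(path, "w") as fh:
        fh.write("# bekit library v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_library_tsv(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_sites(df)
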