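"""Exon-2 transcript space: isoforms, in-silico PCR, frame and IRES logic.

Duplication of DMD exon 2 (Dup2) shifts the reading frame and puts a
premature stop codon in the exon 3 sequence, so cap-dependent translation
fails and no downstream rescue exists.  Skipping both copies (Δ2) also
shifts the frame with a stop in exon 3, but the exon 5 internal ribosome
entry site (IRES) then drives translation from exon 6, producing a highly
functional N-truncated protein — so both the WT (one copy) and Δ2 (zero
copies) transcripts are therapeutic, while Dup2 is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class Exon:
    number: int
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("exon length must be > 0")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(f"exon {self.number}: sequence length "
                                 f"{len(self.sequence)} != declared {self.length}")
            if set(self.sequence) - set("ACGT"):
                raise ValueError(f"exon {self.number}: non-ACGT characters")


@dataclass
class GeneModel:
    """Ordered exon table with the IRES annotation of the DMD 5' region."""

    exons: list[Exon]
    start_codon_exon: int = 1
    start_codon_offset: int = 0                # 0-based offset of ATG within its exon
    ires_exon: int = 5
    ires_translation_start_exon: int = 6

    def __post_init__(self) -> None:
        nums = [e.number for e in self.exons]
        if len(set(nums)) != len(nums) or nums != sorted(nums):
            raise ValueError("exon numbers must be unique and ordered")

    def exon(self, number: int) -> Exon:
        for e in self.exons:
            if e.number == number:
                return e
        raise KeyError(f"exon {number} not in model")

    @property
    def has_sequences(self) -> bool:
        return all(e.sequence is not None for e in self.exons)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        data = json.loads(Path(path).read_text())
        exons = [Exon(number=e["number"], length=e["length"],
                      sequence=e.get("sequence")) for e in data["exons"]]
        return cls(exons=exons,
                   start_codon_exon=data.get("start_codon_exon", 1),
                   start_codon_offset=data.get("start_codon_offset", 0),
                   ires_exon=data.get("ires_exon", 5),
                   ires_translation_start_exon=data.get("ires_translation_start_exon", 6))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneModel":
        """Read exon features from a GFF3-subset exon table.

        Uses ``exon`` lines only; the exon number comes from an
        ``exon_number`` attribute when present, otherwise from the order
        of appearance.  Lengths are end - start + 1 (1-based inclusive
        coordinates); sequences can be attached later from FASTA.
        """
        exons = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8 or fields[2].lower() != "exon":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";")
                         if "=" in kv) if len(fields) > 8 else {}
            number = int(attrs.get("exon_number", len(exons) + 1))
            exons.append(Exon(number=number,
                              length=int(fields[4]) - int(fields[3]) + 1))
        if not exons:
            raise ValueError(f"no exon features found in {path}")
        exons.sort(key=lambda e: e.number)
        return cls(exons=exons)

    def attach_sequences(self, fasta_path: str | Path) -> None:
        """Attach per-exon sequences from a FASTA file.

        Records must be named ``exon_<number>``; every exon in the model
        needs a record of matching length.
        """
        from Bio import SeqIO

        records = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(str(fasta_path), "fasta")}
        for e in self.exons:
            key = f"exon_{e.number}"
            if key not in records:
                raise ValueError(f"FASTA record {key!r} missing")
            seq = records[key]
            if len(seq) != e.length:
                raise ValueError(f"{key}: sequence length {len(seq)} != "
                                 f"declared {e.length}")
            e.sequence = seq


@dataclass
class PrimerPair:
    """RT-PCR primers: forward anchored in exon 1, reverse on the exon 3/4 junction."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            s = seq.upper()
            if not s or set(s) - set("ACGT"):
                raise ValueError(f"{name} primer must be a non-empty ACGT string")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


# Printed assay primers: forward in exon 1, reverse spanning the exon 3/4 junction.
DEFAULT_PRIMERS = PrimerPair(forward="TACCTAAGCCTCCTGGAGCA",
                             reverse="CTTTTGGCAGTTTTTGCCCTGTA")

ISOFORM_NAMES = {0: "D2", 1: "WT", 2: "Dup2"}


@dataclass
class Isoform:
    exon2_copies: int
    name: str
    exon_sequence_order: list[int]
    frame_status: str | None = None            # in_frame | frameshift
    premature_stop_exon: int | None = None
    translation_mode: str | None = None        # cap_dependent | ires_dependent | none

    @property
    def therapeutic(self) -> bool:
        return self.name in ("WT", "D2")

    def spliced_sequence(self, model: GeneModel) -> str:
        if not model.has_sequences:
            raise ValueError("gene model has no sequences")
        return "".join(model.exon(n).sequence for n in self.exon_sequence_order)

    def spliced_length(self, model: GeneModel) -> int:
        return sum(model.exon(n).length for n in self.exon_sequence_order)


def enumerate_isoforms(model: GeneModel, target_exon: int = 2) -> list[Isoform]:
    """The three exon-2 species: Dup2 (2 copies), WT (1), Δ2 (0)."""
    if target_exon not in [e.number for e in model.exons]:
        raise ValueError(f"target exon {target_exon} absent from model")
    base = [e.number for e in model.exons]
    idx = base.index(target_exon)
    isoforms = []
    for copies in (2, 1, 0):
        order = base[:idx] + [target_exon] * copies + base[idx + 1:]
        isoforms.append(Isoform(exon2_copies=copies, name=ISOFORM_NAMES[copies],
                                exon_sequence_order=order))
    return isoforms


def _find_once(haystack: str, needle: str, what: str) -> int:
    first = haystack.find(needle)
    if first < 0:
        raise ValueError(f"{what} primer not found on isoform")
    if haystack.find(needle, first + 1) >= 0:
        raise ValueError(f"{what} primer found more than once on isoform")
    return first


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def amplicon_length(isoform: Isoform, primers: PrimerPair,
                    model: GeneModel) -> int:
    """In-silico PCR product length on the spliced isoform sequence.

    The product runs from the forward primer's 5' end to the reverse
    primer's 5' end inclusive (both primer footprints included, the
    standard PCR convention).  Each primer must bind exactly once.
    """
    seq = isoform.spliced_sequence(model)
    fwd_start = _find_once(seq, primers.forward, "forward")
    rev_site = _revcomp(primers.reverse)
    rev_start = _find_once(seq, rev_site, "reverse")
    if rev_start <= fwd_start:
        raise ValueError("reverse primer binds upstream of forward primer")
    return rev_start + len(rev_site) - fwd_start


def amplicon_lengths_from_geometry(model: GeneModel, target_exon: int = 2,
                                   wt_product: int = 278) -> dict[str, int]:
    """Product lengths in length-only mode, anchored on the WT product size.

    The three products form an arithmetic progression with common
    difference equal to the target exon's length.
    """
    d = model.exon(target_exon).length
    return {"Dup2": wt_product + d, "WT": wt_product, "D2": wt_product - d}


def frame_analysis(isoform: Isoform, model: GeneModel) -> Isoform:
    """Reading-frame scan from the annotated start codon.

    Codons are read from the start codon; the first stop codon and the
    exon containing it are reported.  A stop inside the exon span covered
    by the model (i.e. before the transcript runs out) upstream of the
    final exon marks a frameshift transcript.  Translation mode applies
    the IRES rule: WT translates cap-dependently; Δ2's premature stop is
    rescued by the exon 5 IRES (translation restarting in exon 6); Dup2
    has no rescue.
    """
    seq = isoform.spliced_sequence(model)
    # locate start codon on the isoform: offset of the start exon's first copy
    start = 0
    for n in isoform.exon_sequence_order:
        if n == model.start_codon_exon:
            start += model.start_codon_offset
            break
        start += model.exon(n).length
    else:
        raise ValueError("start codon exon absent from isoform")
    if seq[start:start + 3] != "ATG":
        raise ValueError("no ATG at the annotated start codon position")

    # exon boundaries on the spliced sequence, recording which copy is which
    bounds: list[tuple[int, int, int]] = []   # (begin, end, exon_number)
    pos = 0
    for n in isoform.exon_sequence_order:
        ln = model.exon(n).length
        bounds.append((pos, pos + ln, n))
        pos += ln

    stop_exon: int | None = None
    for i in range(start, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            stop_exon = next(n for b, e, n in bounds if b <= i < e)
            break

    last_exon = isoform.exon_sequence_order[-1]
    premature = stop_exon is not None and stop_exon != last_exon
    isoform.frame_status = "frameshift" if premature else "in_frame"
    isoform.premature_stop_exon = stop_exon if premature else None
    if not premature:
        isoform.translation_mode = "cap_dependent"
    elif isoform.exon2_copies == 0:
        isoform.translation_mode = "ires_dependent"   # exon 5 IRES, start in exon 6
    else:
        isoform.translation_mode = "none"
    return isoform


def classify_therapeutic(fractions) -> dict[str, float]:
    """Per-species and combined therapeutic transcript percentages.

    WT and Δ2 are therapeutic (full-length protein, or IRES-driven
    N-truncated protein); Dup2 is not.
    """
    return {
        "pct_wt": fractions.pct_wt,
        "pct_d2": fractions.pct_d2,
        "pct_dup2": fractions.pct_dup2,
        "pct_therapeutic": fractions.pct_wt + fractions.pct_d2,
    }


def toy_gene_model(exon2_length: int = 62) -> GeneModel:
    """Engineered four-exon toy model reproducing the printed product sizes.

    Synthetic sequences (not the human reference), exon lengths 150, 62,
    80, 60 nt.  The assay primers are embedded so the WT product is 278
    nt (forward primer at a 26-nt offset in exon 1; the reverse-primer
    site spans the exon 3/4 junction, 11 nt in exon 3), hence Dup2 = 340
    and Δ2 = 216.  The ORF starts at an ATG at exon-1 offset 2, has no
    stop codon in the wild-type frame, and exon 3 opens with a block
    carrying stop codons in both shifted frames, so the Dup2 and Δ2
    species reproduce the frameshift-with-stop-in-exon-3 behavior.
    """
    fwd = DEFAULT_PRIMERS.forward                      # 20 nt
    rev_site = _revcomp(DEFAULT_PRIMERS.reverse)       # 23 nt

    # 'C' filler keeps every untouched codon stop-free in every frame.
    e1 = "CC" + "ATG" + "C" * 21 + fwd + "C" * 104     # fwd starts at offset 26
    e2 = "C" * exon2_length                            # 340 - 278 = 62 by default

    # Reading phase in exon 3 (codon starts at local offsets == phase mod 3)
    # depends on the upstream spliced length: 150 + copies * exon2_length.
    def phase(upstream: int) -> int:
        return (2 - upstream) % 3
    p_wt = phase(150 + exon2_length)
    p_d2 = phase(150)
    p_dup2 = phase(150 + 2 * exon2_length)
    shifted = sorted({p_d2, p_dup2} - {p_wt})
    # one TAA per shifted phase, early in exon 3; none lands on a WT codon
    head = ["C"] * 12
    offset = 1
    for ph in shifted:
        while offset % 3 != ph:
            offset += 1
        assert offset + 3 <= len(head)
        head[offset:offset + 3] = "TAA"
        offset += 3
    head = "".join(head)
    for i in range(p_wt, len(head) - 2, 3):            # WT frame stays open
        assert head[i:i + 3] not in STOP_CODONS
    e3 = head + "C" * (80 - len(head) - 11) + rev_site[:11]
    e4 = rev_site[11:] + "C" * (60 - (len(rev_site) - 11))

    return GeneModel(exons=[Exon(1, 150, e1), Exon(2, exon2_length, e2),
                            Exon(3, 80, e3), Exon(4, 60, e4)],
                     start_codon_exon=1, start_codon_offset=2)
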