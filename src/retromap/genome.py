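"""Genome and provirus containers.

A :class:`Genome` is an ordered map of chromosome name to upper-case
nucleotide string over {A, C, G, T, N} plus a per-chromosome mappability
mask of half-open intervals.  A :class:`Provirus` models an integrated
gamma-retroviral genome: two identical LTRs (U3-R-U5) flanking the internal
gag-pol-env sequence, with a splice donor (SD) downstream of the 5' LTR and
the env splice acceptor (env_SA) in the 3' half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, merge_intervals

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered chromosome sequences plus a mappability mask."""

    sequences: dict[str, str]
    mappable: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate chromosome names")
        for chrom, seq in self.sequences.items():
            ivs = self.mappable.get(chrom)
            if ivs is None:
                self.mappable[chrom] = [(0, len(seq))] if seq else []
            else:
                merged = merge_intervals(ivs)
                for s, e in merged:
                    if s < 0 or e > len(seq):
                        raise ValueError(
                            f"mask interval ({s}, {e}) outside {chrom} of length {len(seq)}"
                        )
                self.mappable[chrom] = merged

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(sequences=seqs)


@dataclass
class Provirus:
    """Proviral sequence with named element intervals in provirus coordinates.

    Element keys: ``5U3 5R 5U5 SD env_SA 3U3 3R 3U5`` (half-open intervals).
    Invariants: within each LTR U3 < R < U5 and the intervals abut; the two
    LTR sequences are identical; SD lies between the 5' U5 end and env_SA.
    """

    name: str
    sequence: str
    elements: dict[str, Interval]

    def __post_init__(self) -> None:
        el = self.elements
        required = {"5U3", "5R", "5U5", "SD", "env_SA", "3U3", "3R", "3U5"}
        missing = required - set(el)
        if missing:
            raise ValueError(f"missing provirus elements: {sorted(missing)}")
        for prefix in ("5", "3"):
            u3, r, u5 = el[f"{prefix}U3"], el[f"{prefix}R"], el[f"{prefix}U5"]
            if not (u3[1] == r[0] and r[1] == u5[0]):
                raise ValueError(f"{prefix}' LTR elements must abut in order U3 < R < U5")
        if self.ltr5_seq() != self.ltr3_seq():
            raise ValueError("5' and 3' LTR sequences differ")
        if not (el["5U5"][1] <= el["SD"][0] and el["SD"][1] <= el["env_SA"][0]):
            raise ValueError("SD must lie between the 5' U5 end and env_SA")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ltr_len(self) -> int:
        return self.elements["5U5"][1] - self.elements["5U3"][0]

    def ltr5_seq(self) -> str:
        return self.sequence[self.elements["5U3"][0] : self.elements["5U5"][1]]

    def ltr3_seq(self) -> str:
        return self.sequence[self.elements["3U3"][0] : self.elements["3U5"][1]]

    @property
    def ltr_seq(self) -> str:
        return self.ltr5_seq()

    def write_fasta(self, path) -> None:
        SeqIO.write([SeqRecord(Seq(self.sequence), id=self.name, description="")],
                    str(path), "fasta")

    def write_elements_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\n")
            for name, (s, e) in sorted(self.elements.items(), key=lambda kv: kv[1]):
                fh.write(f"{name}\t{s}\t{e}\n")
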