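"""Aligned sequencing fragments and their BED interchange format.

Fragments are stored columnar (numpy arrays) because realistic simulations
carry 10^5-10^6 of them.  Each fragment has one or two aligned blocks on a
single replicon:

* one block — an ordinary collinear alignment;
* two blocks — either a circular wrap-around split (the fragment crosses the
  arbitrary coordinate origin of a circular genome) or a chimeric junction
  fragment spanning a structural rearrangement breakpoint.

Blocks of two-block fragments are kept in genomic order (lower start first).
For chimeras the simulator emits block strands in the canonical orientation
(as sampled from the forward strand of the rearranged molecule), so that on
an inverted segment a genomically ordered ``(+,-)`` pair is a head-to-head
junction and ``(-,+)`` a tail-to-tail junction.

On disk, single-block fragments are BED6 rows (score 0) and two-block
fragments are BED12-style rows with ``blockCount=2``; because BED has a
single strand column, per-block strands ride in the name field as
``name;s1=+,s2=-`` (s1 = genomically first block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Block:
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class AlignedFragment:
    """Row view of a :class:`FragmentSet`; convenient in tests and small inputs."""

    chrom: str
    blocks: tuple  # 1 or 2 Block
    name: str = ""

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


class FragmentInputError(ValueError):
    """Malformed fragment record; message names the offending line/record."""


def _strand_codes(strands) -> np.ndarray:
    return np.where(np.asarray(strands) == "-", -1, 1).astype(np.int8)


class FragmentSet:
    """Columnar container of aligned fragments on a single replicon.

    Attributes
    ----------
    b1_start, b1_end : int64 arrays
        First (genomically lower) block, half-open.
    b1_strand : int8 array, +1 / -1
    b2_start, b2_end, b2_strand
        Second block; ``b2_start == -1`` marks single-block fragments.
    """

    def __init__(self, chrom, b1_start, b1_end, b1_strand,
                 b2_start=None, b2_end=None, b2_strand=None):
        n = len(b1_start)
        self.chrom = chrom
        self.b1_start = np.asarray(b1_start, dtype=np.int64)
        self.b1_end = np.asarray(b1_end, dtype=np.int64)
        self.b1_strand = np.asarray(b1_strand, dtype=np.int8)
        if b2_start is None:
            b2_start = np.full(n, -1, dtype=np.int64)
            b2_end = np.full(n, -1, dtype=np.int64)
            b2_strand = np.zeros(n, dtype=np.int8)
        self.b2_start = np.asarray(b2_start, dtype=np.int64)
        self.b2_end = np.asarray(b2_end, dtype=np.int64)
        self.b2_strand = np.asarray(b2_strand, dtype=np.int8)
        if not (len(self.b1_end) == len(self.b1_strand) == len(self.b2_start)
                == len(self.b2_end) == len(self.b2_strand) == n):
            raise ValueError("column length mismatch")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.b1_start)

    @property
    def is_chimeric(self) -> np.ndarray:
        return self.b2_start >= 0

    @property
    def total_bases(self) -> int:
        chim = self.is_chimeric
        total = int((self.b1_end - self.b1_start).sum())
        total += int((self.b2_end[chim] - self.b2_start[chim]).sum())
        return total

    def validate(self, L: int) -> None:
        """Check all block coordinates lie in [0, L]; raise naming the record."""
        chim = self.is_chimeric
        bad = (self.b1_start < 0) | (self.b1_start >= self.b1_end) | (self.b1_end > L)
        bad |= chim & ((self.b2_start >= self.b2_end) | (self.b2_end > L))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FragmentInputError(
                f"fragment #{i} has blocks outside [0, {L}): "
                f"b1=[{self.b1_start[i]},{self.b1_end[i]}) "
                f"b2=[{self.b2_start[i]},{self.b2_end[i]})"
            )

    def block_arrays(self):
        """All aligned blocks flattened: (starts, ends) including second blocks."""
        chim = self.is_chimeric
        starts = np.concatenate([self.b1_start, self.b2_start[chim]])
        ends = np.concatenate([self.b1_end, self.b2_end[chim]])
        return starts, ends

    def subset(self, index) -> "FragmentSet":
        return FragmentSet(self.chrom, self.b1_start[index], self.b1_end[index],
                           self.b1_strand[index], self.b2_start[index],
                           self.b2_end[index], self.b2_strand[index])

    @staticmethod
    def empty(chrom: str) -> "FragmentSet":
        z = np.empty(0, dtype=np.int64)
        return FragmentSet(chrom, z, z, z.astype(np.int8))

    @staticmethod
    def concat(parts) -> "FragmentSet":
        parts = list(parts)
        if not parts:
            raise ValueError("nothing to concatenate")
        chrom = parts[0].chrom
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            return FragmentSet.empty(chrom)
        return FragmentSet(
            chrom,
            np.concatenate([p.b1_start for p in parts]),
            np.concatenate([p.b1_end for p in parts]),
            np.concatenate([p.b1_strand for p in parts]),
            np.concatenate([p.b2_start for p in parts]),
            np.concatenate([p.b2_end for p in parts]),
            np.concatenate([p.b2_strand for p in parts]),
        )

    @staticmethod
    def from_fragments(chrom: str, fragments) -> "FragmentSet":
        """Build from an iterable of :class:`AlignedFragment` (genomic block order)."""
        b1s, b1e, b1st, b2s, b2e, b2st = [], [], [], [], [], []
        for fr in fragments:
            blocks = sorted(fr.blocks, key=lambda b: b.start)
            b1s.append(blocks[0].start)
            b1e.append(blocks[0].end)
            b1st.append(1 if blocks[0].strand == "+" else -1)
            if len(blocks) == 2:
                b2s.append(blocks[1].start)
                b2e.append(blocks[1].end)
                b2st.append(1 if blocks[1].strand == "+" else -1)
            else:
                b2s.append(-1)
                b2e.append(-1)
                b2st.append(0)
        return FragmentSet(chrom, b1s, b1e, b1st, b2s, b2e, b2st)

    def __iter__(self):
        sym = {1: "+", -1: "-"}
        for i in range(len(self)):
            blocks = [Block(int(self.b1_start[i]), int(self.b1_end[i]),
                            sym[int(self.b1_strand[i])])]
            if self.b2_start[i] >= 0:
                blocks.append(Block(int(self.b2_start[i]), int(self.b2_end[i]),
                                    sym[int(self.b2_strand[i])]))
            yield AlignedFragment(self.chrom, tuple(blocks), name=f"frag{i}")

    # -- BED interchange ---------------------------------------------------
    def to_bed(self, path) -> None:
        sym = {1: "+", -1: "-", 0: "."}
        with open(path, "w") as fh:
            for i in range(len(self)):
                s1, e1 = int(self.b1_start[i]), int(self.b1_end[i])
                st1 = sym[int(self.b1_strand[i])]
                if self.b2_start[i] < 0:
                    fh.write(f"{self.chrom}\t{s1}\t{e1}\tfrag{i}\t0\t{st1}\n")
                    continue
                s2, e2 = int(self.b2_start[i]), int(self.b2_end[i])
                st2 = sym[int(self.b2_strand[i])]
                cstart, cend = s1, max(e1, e2)
                name = f"frag{i};s1={st1},s2={st2}"
                sizes = f"{e1 - s1},{e2 - s2}"
                offs = f"{s1 - cstart},{s2 - cstart}"
                fh.write(
                    f"{self.chrom}\t{cstart}\t{cend}\t{name}\t0\t{st1}\t"
                    f"{cstart}\t{cend}\t0\t2\t{sizes}\t{offs}\n"
                )

    @staticmethod
    def from_bed(path) -> "FragmentSet":
        chrom = None
        cols = ([], [], [], [], [], [])
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise FragmentInputError(f"{path}:{lineno}: expected >=6 BED columns")
                if chrom is None:
                    chrom = f[0]
                elif f[0] != chrom:
                    raise FragmentInputError(
                        f"{path}:{lineno}: multiple chromosomes ({chrom!r}, {f[0]!r}); "
                        "expected a single replicon"
                    )
                try:
                    cstart, cend = int(f[1]), int(f[2])
                except ValueError as exc:
                    raise FragmentInputError(f"{path}:{lineno}: bad coordinates") from exc
                if len(f) < 12 or f[9] == "1":
                    cols[0].append(cstart)
                    cols[1].append(cend)
                    cols[2].append(1 if f[5] != "-" else -1)
                    cols[3].append(-1)
                    cols[4].append(-1)
                    cols[5].append(0)
                    continue
                if f[9] != "2":
                    raise FragmentInputError(
                        f"{path}:{lineno}: blockCount={f[9]}; only 1 or 2 supported"
                    )
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                name = f[3]
                try:
                    tag = name.split(";", 1)[1]
                    st = dict(kv.split("=") for kv in tag.split(","))
                    st1, st2 = st["s1"], st["s2"]
                except (IndexError, KeyError, ValueError) as exc:
                    raise FragmentInputError(
                        f"{path}:{lineno}: two-block record {name!r} lacks "
                        "';s1=..,s2=..' strand tag"
                    ) from exc
                cols[0].append(cstart + offs[0])
                cols[1].append(cstart + offs[0] + sizes[0])
                cols[2].append(1 if st1 != "-" else -1)
                cols[3].append(cstart + offs[1])
                cols[4].append(cstart + offs[1] + sizes[1])
                cols[5].append(1 if st2 != "-" else -1)
        if chrom is None:
            chrom = "unknown"
        return FragmentSet(chrom, *cols)

    # -- minimal SAM export ------------------------------------------------
    def to_sam(self, path, genome_length: int) -> None:
        """Plain-text SAM with sequence-free records (SEQ/QUAL '*').

        Chimeric fragments appear as a primary plus a supplementary alignment
        linked by an ``SA`` tag, the dialect most SV callers expect.
        """
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{self.chrom}\tLN:{genome_length}\n")
            for i in range(len(self)):
                s1, e1 = int(self.b1_start[i]), int(self.b1_end[i])
                flag1 = 16 if self.b1_strand[i] < 0 else 0
                cigar1 = f"{e1 - s1}M"
                if self.b2_start[i] < 0:
                    fh.write(f"frag{i}\t{flag1}\t{self.chrom}\t{s1 + 1}\t60\t"
                             f"{cigar1}\t*\t0\t0\t*\t*\n")
                    continue
                s2, e2 = int(self.b2_start[i]), int(self.b2_end[i])
                flag2 = (16 if self.b2_strand[i] < 0 else 0) | 2048
                cigar2 = f"{e2 - s2}M"
                sa2 = f"{self.chrom},{s2 + 1},{'-' if self.b2_strand[i] < 0 else '+'},{cigar2},60,0;"
                sa1 = f"{self.chrom},{s1 + 1},{'-' if self.b1_strand[i] < 0 else '+'},{cigar1},60,0;"
                fh.write(f"frag{i}\t{flag1}\t{self.chrom}\t{s1 + 1}\t60\t"
                         f"{cigar1}\t*\t0\t0\t*\t*\tSA:Z:{sa2}\n")
                fh.write(f"frag{i}\t{flag2}\t{self.chrom}\t{s2 + 1}\t60\t"
                         f"{cigar2}\t*\t0\t0\t*\t*\tSA:Z:{sa1}\n")
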