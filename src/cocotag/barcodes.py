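"""Barcode whitelists, stream assignment and well-ID rewriting.

The assay tagmentes cells in a 96-well plate with two transposase plates,
each loaded as an 8x12 grid: the first plate carries s5 adapter barcodes
1-8 (rows) and s7 barcodes 1-12 (columns); the second plate carries s5
barcodes 9-16 and s7 barcodes 13-24 over the same physical wells.  A cell
in well (row, column) can therefore emit four s5/s7 barcode combinations:

==========  ===========  ==========================================
s5 index    s7 index     stream
==========  ===========  ==========================================
1-8         1-12         ``target1``  (first transposase only)
9-16        13-24        ``target2``  (second transposase only)
1-8         13-24        ``co1``      (co-occupancy, orientation 1)
9-16        1-12         ``co2``      (co-occupancy, orientation 2)
==========  ===========  ==========================================

Nanowell p5/p7 index barcodes (72 each) added by PCR complete the cell
barcode.  ``well_id`` collapses the four adapter combinations of one well
into a single plate coordinate so that all four streams of a physical cell
share one barcode.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STREAMS = ("target1", "target2", "co1", "co2")
UNASSIGNED = "unassigned"

_ROWS = string.ascii_uppercase[:8]  # A..H <-> s5 rank 1..8

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def match_barcode(observed: str, whitelist: list[str], max_mismatch: int = 1) -> int | None:
    """Return the 0-based whitelist index of the unique best hit.

    A hit requires Hamming distance <= ``max_mismatch``; if two or more
    whitelist entries tie at the minimal distance the observation is
    ambiguous and ``None`` is returned.  Whitelist entries must have the
    same length as the observed sequence.
    """
    best, best_idx, n_best = max_mismatch + 1, None, 0
    for i, wl in enumerate(whitelist):
        d = hamming(observed, wl)
        if d < best:
            best, best_idx, n_best = d, i, 1
        elif d == best:
            n_best += 1
    if best_idx is None or n_best > 1:
        return None
    return best_idx


def assign_stream(s5_index: int, s7_index: int) -> str:
    """Map 1-based adapter-barcode indices to a read stream."""
    if not 1 <= s5_index <= 16:
        raise ValueError(f"s5 index out of range 1-16: {s5_index}")
    if not 1 <= s7_index <= 24:
        raise ValueError(f"s7 index out of range 1-24: {s7_index}")
    set_a5 = s5_index <= 8
    set_a7 = s7_index <= 12
    if set_a5 and set_a7:
        return "target1"
    if not set_a5 and not set_a7:
        return "target2"
    if set_a5:
        return "co1"
    return "co2"


def well_id(s5_index: int, s7_index: int) -> str:
    """Plate coordinate (e.g. ``C7``) shared by all four combinations of a well."""
    assign_stream(s5_index, s7_index)  # range check
    row = s5_index if s5_index <= 8 else s5_index - 8
    col = s7_index if s7_index <= 12 else s7_index - 12
    return f"{_ROWS[row - 1]}{col}"


@dataclass
class BarcodeScheme:
    """Whitelists plus barcode layout within the two index reads.

    ``s5`` holds the 16 s5 sequences in index order (positions 0-7 = set A,
    8-15 = set B); ``s7`` the 24 s7 sequences (0-11 = set A, 12-23 = set B).
    ``p5_wells``/``p7_wells`` are the nanowell index whitelists.  Offsets
    give the start of each barcode inside its index read: index read 1
    carries (s7, p7), index read 2 carries (s5, p5), mirroring a dual-index
    layout where the adapter barcode precedes the nanowell barcode.
    """

    s5: list[str]
    s7: list[str]
    p5_wells: list[str]
    p7_wells: list[str]
    max_mismatch: int = 1
    i1_s7_offset: int = 0
    i1_p7_offset: int | None = None  # default: right after s7
    i2_s5_offset: int = 0
    i2_p5_offset: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.s5) != 16:
            raise ValueError("s5 whitelist must have 16 sequences")
        if len(self.s7) != 24:
            raise ValueError("s7 whitelist must have 24 sequences")
        if self.i1_p7_offset is None:
            self.i1_p7_offset = self.i1_s7_offset + len(self.s7[0])
        if self.i2_p5_offset is None:
            self.i2_p5_offset = self.i2_s5_offset + len(self.s5[0])
        self.validate()

    # -- properties ---------------------------------------------------
    @property
    def s5_len(self) -> int:
        return len(self.s5[0])

    @property
    def s7_len(self) -> int:
        return len(self.s7[0])

    @property
    def p5_len(self) -> int:
        return len(self.p5_wells[0])

    @property
    def p7_len(self) -> int:
        return len(self.p7_wells[0])

    def validate(self) -> None:
        """Check uniqueness and separation of every whitelist.

        Barcodes read at the same position must be pairwise separated by
        Hamming distance > 2*max_mismatch, otherwise a max_mismatch-ball
        around an observation could contain two whitelist members.
        """
        for name, wl in (
            ("s5", self.s5),
            ("s7", self.s7),
            ("p5_wells", self.p5_wells),
            ("p7_wells", self.p7_wells),
        ):
            if len({len(s) for s in wl}) != 1:
                raise ValueError(f"{name}: sequences differ in length")
            if len(set(wl)) != len(wl):
                raise ValueError(f"{name}: duplicate sequences")
            floor = 2 * self.max_mismatch
            for i in range(len(wl)):
                for j in range(i + 1, len(wl)):
                    if hamming(wl[i], wl[j]) <= floor:
                        raise ValueError(
                            f"{name}: sequences {i} and {j} are within "
                            f"Hamming distance {floor} (need > 2*max_mismatch)"
                        )

    # -- barcode extraction -------------------------------------------
    def _matcher(self, name: str, whitelist: list[str]):
        """Memoized matcher with an exact-lookup fast path."""
        cache = self.extra.setdefault("_matchers", {})
        if name not in cache:
            exact = {seq: i for i, seq in enumerate(whitelist)}
            memo: dict[str, int | None] = {}

            def match(obs: str) -> int | None:
                hit = exact.get(obs)
                if hit is not None:
                    return hit
                if obs in memo:
                    return memo[obs]
                res = match_barcode(obs, whitelist, self.max_mismatch)
                memo[obs] = res
                return res

            cache[name] = match
        return cache[name]

    def parse_index_reads(self, i1: str, i2: str) -> tuple[int | None, int | None, int | None, int | None]:
        """Extract and match (s5, s7, p5, p7) 1-based indices from index reads."""
        s7_obs = i1[self.i1_s7_offset : self.i1_s7_offset + self.s7_len]
        p7_obs = i1[self.i1_p7_offset : self.i1_p7_offset + self.p7_len]
        s5_obs = i2[self.i2_s5_offset : self.i2_s5_offset + self.s5_len]
        p5_obs = i2[self.i2_p5_offset : self.i2_p5_offset + self.p5_len]
        s5 = self._matcher("s5", self.s5)(s5_obs)
        s7 = self._matcher("s7", self.s7)(s7_obs)
        p5 = self._matcher("p5", self.p5_wells)(p5_obs)
        p7 = self._matcher("p7", self.p7_wells)(p7_obs)
        to1 = lambda v: None if v is None else v + 1
        return to1(s5), to1(s7), to1(p5), to1(p7)

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "s5": self.s5,
            "s7": self.s7,
            "p5_wells": self.p5_wells,
            "p7_wells": self.p7_wells,
            "max_mismatch": self.max_mismatch,
            "i1_s7_offset": self.i1_s7_offset,
            "i1_p7_offset": self.i1_p7_offset,
            "i2_s5_offset": self.i2_s5_offset,
            "i2_p5_offset": self.i2_p5_offset,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BarcodeScheme":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def synthetic(cls, seed: int = 0, barcode_len: int = 8, well_len: int = 10,
                  max_mismatch: int = 1, n_wells: int = 72) -> "BarcodeScheme":
        """Deterministic random scheme meeting the separation invariant.

        Real adapter/nanowell sequences are vendor-specific; this generator
        produces a valid stand-in whitelist for simulation and testing.
        """
        rng = np.random.default_rng(seed)
        floor = 2 * max_mismatch

        def draw(n: int, length: int) -> list[str]:
            out: list[np.ndarray] = []
            while len(out) < n:
                cand = _BASES[rng.integers(0, 4, size=length)]
                if all(int((cand != prev).sum()) > floor for prev in out):
                    out.append(cand)
            return [bytes(c).decode() for c in out]

        # s5 and s7 are read at different offsets than p5/p7, so separation
        # is enforced within each whitelist independently.
        return cls(
            s5=draw(16, barcode_len),
            s7=draw(24, barcode_len),
            p5_wells=draw(n_wells, well_len),
            p7_wells=draw(n_wells, well_len),
            max_mismatch=max_mismatch,
        )


def cell_barcode(well: str, p5_index: int, p7_index: int) -> str:
    """Rewritten cell barcode: plate well + nanowell p5/p7 indices."""
    return f"{well}+{p5_index:02d}+{p7_index:02d}"
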