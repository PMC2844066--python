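"""SPOT-style overlapping peptide scans and interval-logic epitope calling.

A peptide scan tiles a region of the antigen with fixed-length peptides at
a fixed step (here 15-mers every 5 residues, so adjacent peptides overlap
by 10). A spot is positive when the immobilized peptide binds the
antibody, which for a linear epitope requires the peptide span to contain
the whole epitope. The epitope is therefore bracketed by

* the intersection of all positive spans (the *core* — the epitope must
  sit inside every positive peptide), and
* for every negative peptide overlapping the core, the requirement that
  the epitope reach into ``core \\ negative`` (otherwise that spot would
  have been positive too).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import ProteinSequence, SequenceRegion, extract_region


class ScanDesignError(ValueError):
    pass


@dataclass
class ScanDesign:
    """Ordered peptide tiling of ``scan_region`` with 1-based spot indices."""

    parent_id: str
    scan_region: SequenceRegion
    peptide_length: int
    step: int
    anchor_c: bool
    peptides: list[SequenceRegion]

    @property
    def n_spots(self) -> int:
        return len(self.peptides)

    def peptide(self, spot: int) -> SequenceRegion:
        if not 1 <= spot <= len(self.peptides):
            raise ScanDesignError(f"spot {spot} outside 1..{len(self.peptides)}")
        return self.peptides[spot - 1]


@dataclass
class SpotReactivity:
    """Spot intensities with a positive/negative threshold.

    Intensities are arbitrary units >= 0; a spot is positive when its
    intensity strictly exceeds the threshold.
    """

    intensities: dict[int, float]
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be >= 0")

    def positive_spots(self) -> list[int]:
        return sorted(i for i, v in self.intensities.items() if v > self.threshold)

    def negative_spots(self) -> list[int]:
        return sorted(i for i, v in self.intensities.items() if v <= self.threshold)


@dataclass
class EpitopeCall:
    """Result of interval-logic epitope calling on one scan."""

    core: SequenceRegion | None
    must_include: list[SequenceRegion] = field(default_factory=list)
    consistent: bool = False
    no_signal: bool = False
    note: str = ""


def design_scan(
    region: SequenceRegion,
    length: int = 15,
    step: int = 5,
    anchor_c: bool = True,
    parent_id: str = "",
) -> ScanDesign:
    """Tile ``region`` with ``length``-mers every ``step`` residues.

    Peptides start at region.start, region.start+step, ... while they fit;
    with ``anchor_c``, if the last tile stops short of region.end one extra
    peptide ending exactly at region.end is appended (standard SPOT
    practice so the C-terminus is covered).
    """
    if step < 1:
        raise ScanDesignError("step must be >= 1")
    if length > len(region):
        raise ScanDesignError(
            f"peptide length {length} exceeds region size {len(region)}"
        )
    peptides = []
    start = region.start
    while start + length - 1 <= region.end:
        peptides.append(SequenceRegion(start, start + length - 1))
        start += step
    if anchor_c and peptides[-1].end < region.end:
        peptides.append(SequenceRegion(region.end - length + 1, region.end))
    return ScanDesign(parent_id, region, length, step, anchor_c, peptides)


def threshold_from_intensities(values: "list[float] | np.ndarray") -> float:
    """Automatic positive/negative split: mean + 2·SD of the lowest quartile.

    The lowest quartile of spots is assumed to be background; anything more
    than two background standard deviations above the background mean is
    called positive.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("no intensities")
    k = max(1, arr.size // 4)
    low = arr[:k]
    return float(low.mean() + 2.0 * low.std())


def call_epitope(
    scan: ScanDesign,
    reactivity: SpotReactivity,
    prior: SequenceRegion | None = None,
) -> EpitopeCall:
    """Call an epitope from spot reactivity by interval logic.

    The core is the intersection of all positive peptide spans, optionally
    intersected with a ``prior`` region (e.g. the immunogen peptide). For
    each negative peptide overlapping the core, the parts of the core
    outside that peptide are recorded as must-include constraints; a
    negative peptide that covers the whole core is a contradiction and
    marks the call inconsistent. No positive spot yields a distinct
    no-signal result.
    """
    unknown = set(reactivity.intensities) - set(range(1, scan.n_spots + 1))
    if unknown:
        raise ScanDesignError(f"reactivity refers to unknown spots {sorted(unknown)}")
    positives = reactivity.positive_spots()
    if not positives:
        return EpitopeCall(None, [], consistent=False, no_signal=True,
                          note="no positive spot")
    core: SequenceRegion | None = scan.peptide(positives[0])
    for spot in positives[1:]:
        core = core.intersect(scan.peptide(spot))
        if core is None:
            return EpitopeCall(None, [], consistent=False,
                              note="positive peptides have empty intersection")
    if prior is not None:
        core = core.intersect(prior)
        if core is None:
            return EpitopeCall(None, [], consistent=False,
                              note="prior region excludes the scan core")
    must_include: list[SequenceRegion] = []
    for spot in reactivity.negative_spots():
        neg = scan.peptide(spot)
        if not neg.overlaps(core):
            continue
        rest = core.subtract(neg)
        if not rest:
            return EpitopeCall(core, [], consistent=False,
                              note=f"negative spot {spot} covers the entire core")
        must_include.extend(rest)
    must_include = sorted(set(must_include))
    return EpitopeCall(core, must_include, consistent=True)


def scan_to_table(scan: ScanDesign, parent: ProteinSequence) -> str:
    """Per-spot tab-separated table: index, start, end, peptide sequence."""
    lines = ["spot\tstart\tend\tpeptide"]
    for i, region in enumerate(scan.peptides, 1):
        lines.append(
            f"{i}\t{region.start}\t{region.end}\t{extract_region(parent, region)}"
        )
    return "\n".join(lines) + "\n"


def scan_to_fasta(scan: ScanDesign, parent: ProteinSequence) -> str:
    """Spot peptides as FASTA records named ``<parent>_spot<i>``."""
    out = []
    for i, region in enumerate(scan.peptides, 1):
        out.append(f">{parent.id}_spot{i} {region.start}-{region.end}")
        out.append(extract_region(parent, region))
    return "\n".join(out) + "\n"


def read_reactivity(text: str, threshold: float | None = None) -> SpotReactivity:
    """Parse spot reactivity from two-column text.

    Accepts either (spot index, intensity) or (spot index, +/-) rows; in
    +/- mode intensities are coded 1/0 with threshold 0.5. When
    ``threshold`` is None in intensity mode it is derived with
    :func:`threshold_from_intensities`.
    """
    pairs: list[tuple[int, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx, value = line.split()[:2]
        pairs.append((int(idx), value))
    if not pairs:
        raise ValueError("empty reactivity table")
    if all(v in {"+", "-"} for _, v in pairs):
        return SpotReactivity(
            {i: (1.0 if v == "+" else 0.0) for i, v in pairs}, threshold=0.5
        )
    intensities = {i: float(v) for i, v in pairs}
    if threshold is None:
        threshold = threshold_from_intensities(list(intensities.values()))
    return SpotReactivity(intensities, threshold)
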