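"""Formic-acid (Asp-Pro) chemical cleavage and fragment-based epitope localization.

Concentrated formic acid selectively cleaves acid-labile aspartate-proline
peptide bonds. On a chain with cleavage sites after residues p1 < p2 < ...
an incomplete digest yields every fragment whose ends are cleavage
boundaries (or chain termini); the number of uncut internal sites is the
fragment's missed-cleavage count. Antibody reactivity against blotted
fragments then brackets an epitope: the epitope must lie inside every
reactive fragment, so the intersection of reactive fragment regions is the
tightest interval consistent with the blot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _ptmass

from .sequences import ProteinSequence, RegionError, SequenceRegion, extract_region, find_motif

WATER_AVERAGE_DA = 18.0153


class DigestError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageSite:
    """Cut between residues ``position`` and ``position + 1``.

    For Asp-Pro chemistry, residue ``position`` is D and ``position + 1``
    is P; the published bonds "β31-32 and β304-305" are sites 31 and 304.
    """

    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DigestError(f"invalid cleavage site {self.position}")


@dataclass(frozen=True)
class Fragment:
    region: SequenceRegion
    missed_cleavages: int
    label: str
    mass_da: float | None = None


@dataclass
class FragmentReactivity:
    """Presence/absence blot readout for one antibody."""

    antibody: str
    reactive: set[str]
    non_reactive: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.reactive & self.non_reactive
        if overlap:
            raise ValueError(f"labels both reactive and non-reactive: {overlap}")


def find_cleavage_sites(seq: ProteinSequence, motif: str = "DP") -> list[CleavageSite]:
    """Asp-Pro sites: a DP at 1-based position p is a cut after residue p."""
    return [CleavageSite(p) for p in find_motif(seq, motif)]


def fragment_mass(
    seq: ProteinSequence,
    region: SequenceRegion,
    average: bool = True,
    unknown_residue_mass: float | None = None,
) -> float:
    """Peptide mass in Daltons (average by default, for SDS-PAGE context).

    ``X`` residues raise unless ``unknown_residue_mass`` (a residue, i.e.
    water-free, mass) is configured.
    """
    peptide = extract_region(seq, region)
    n_x = peptide.count("X")
    if n_x and unknown_residue_mass is None:
        raise ValueError(
            f"region {region} contains 'X'; set unknown_residue_mass to proceed"
        )
    core = peptide.replace("X", "")
    if core:
        m = _ptmass.calculate_mass(sequence=core, average=average)
    else:
        m = WATER_AVERAGE_DA
    return float(m + n_x * (unknown_residue_mass or 0.0))


def _label_fragments(base: list[SequenceRegion], prefix: str) -> dict[SequenceRegion, str]:
    """Name complete-digest fragments by descending length: β1 is the largest.

    Mirrors the gel-band naming convention where the heaviest fragment is
    numbered first.
    """
    order = sorted(base, key=lambda r: (-len(r), r.start))
    return {r: f"{prefix}{i}" for i, r in enumerate(order, 1)}


def digest(
    seq: ProteinSequence,
    sites: list[CleavageSite],
    max_missed: int = 0,
    label_prefix: str = "β",
    with_mass: bool = False,
) -> list[Fragment]:
    """Enumerate digest fragments with up to ``max_missed`` missed cleavages.

    Fragments are every interval [a, b] whose boundaries a-1 and b are
    cleavage sites or chain termini with at most ``max_missed`` uncut sites
    strictly inside; the intact chain is included only when its own
    internal-site count passes the same filter. Sorted by (start, end).
    Composite fragments are labelled by joining their constituent
    complete-digest labels (e.g. "β1+β2").
    """
    if max_missed < 0:
        raise DigestError("max_missed must be >= 0")
    length = len(seq)
    positions = sorted(s.position for s in sites)
    if len(set(positions)) != len(positions):
        raise DigestError("duplicate cleavage sites")
    for p in positions:
        if p >= length:
            raise DigestError(f"cleavage site {p} outside sequence of length {length}")
    boundaries = [0] + positions + [length]
    base_regions = [
        SequenceRegion(boundaries[i] + 1, boundaries[i + 1])
        for i in range(len(boundaries) - 1)
    ]
    base_labels = _label_fragments(base_regions, label_prefix)
    fragments: list[Fragment] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            missed = j - i - 1
            if missed > max_missed:
                continue
            region = SequenceRegion(boundaries[i] + 1, boundaries[j])
            parts = base_regions[i:j]
            label = "+".join(
                base_labels[r] for r in sorted(parts, key=lambda r: base_labels[r])
            )
            m = fragment_mass(seq, region) if with_mass else None
            fragments.append(Fragment(region, missed, label, m))
    fragments.sort(key=lambda f: (f.region.start, f.region.end))
    return fragments


def epitope_to_fragments(
    epitope: SequenceRegion, fragments: list[Fragment]
) -> set[str]:
    """Labels of every fragment whose region fully contains the epitope."""
    return {f.label for f in fragments if f.region.contains(epitope)}


@dataclass
class LocalizationResult:
    antibody: str
    region: SequenceRegion | None
    consistent: bool
    note: str = ""


def consistent_region(
    reactivity: FragmentReactivity, fragments: list[Fragment]
) -> LocalizationResult:
    """Intersect reactive fragment regions to bracket the epitope.

    Flags inconsistency when the intersection is empty or lies entirely
    inside a fragment reported non-reactive (a reactive antibody should
    have stained that fragment too).
    """
    by_label = {f.label: f for f in fragments}
    missing = (reactivity.reactive | reactivity.non_reactive) - set(by_label)
    if missing:
        raise ValueError(f"unknown fragment labels: {sorted(missing)}")
    if not reactivity.reactive:
        raise ValueError("at least one reactive fragment is required")
    labels = sorted(reactivity.reactive)
    core: SequenceRegion | None = by_label[labels[0]].region
    for label in labels[1:]:
        core = core.intersect(by_label[label].region)
        if core is None:
            return LocalizationResult(
                reactivity.antibody, None, False,
                "reactive fragments have empty intersection",
            )
    for label in sorted(reactivity.non_reactive):
        if by_label[label].region.contains(core):
            return LocalizationResult(
                reactivity.antibody, core, False,
                f"intersection lies inside non-reactive fragment {label}",
            )
    return LocalizationResult(reactivity.antibody, core, True)


def digest_table(fragments: list[Fragment]) -> str:
    """Tab-separated digest report."""
    lines = ["label\tstart\tend\tlength\tmissed_cleavages\tmass_Da"]
    for f in fragments:
        m = f"{f.mass_da:.2f}" if f.mass_da is not None else "NA"
        lines.append(
            f"{f.label}\t{f.region.start}\t{f.region.end}\t{len(f.region)}"
            f"\t{f.missed_cleavages}\t{m}"
        )
    return "\n".join(lines) + "\n"


def read_reactivity_table(text: str) -> list[FragmentReactivity]:
    """Parse a two-column text table: antibody, comma-separated reactive labels.

    An optional third column lists non-reactive labels. Lines starting with
    '#' are comments.
    """
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed reactivity line: {line!r}")
        antibody = parts[0].strip()
        reactive = {p.strip() for p in parts[1].split(",") if p.strip()}
        non_reactive = set()
        if len(parts) > 2:
            non_reactive = {p.strip() for p in parts[2].split(",") if p.strip()}
        out.append(FragmentReactivity(antibody, reactive, non_reactive))
    return out
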