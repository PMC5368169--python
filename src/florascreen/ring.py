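"""RING ubiquitin-ligase domain identification and classification.

The canonical RING zinc-binding domain carries eight metal-ligand residues
(two interleaved zinc-coordination sites) with conserved spacing:

    M1-x2-M2-x(9..39)-M3-x(1..3)-M4-x(2..3)-M5-x2-M6-x(4..48)-M7-x2-M8

Ligand positions 1, 2, 3, 6, 7 and 8 are cysteines in the canonical family;
positions 4 and 5 vary (C/H/D/S/T) and define the subtype (HC = C3HC4,
H2 = C3H2C3, v = CH, C2, D, S/T).  Domain candidates come from
InterProScan-style annotation tables; ligand location then validates the
spacing directly on the sequence and the subtype is read from an editable
rule table.  A gene-set reconciliation helper partitions a previous
family census against the current one with per-gene evidence codes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "SIGNATURE_DBS",
    "DomainAnnotation",
    "RingDomainHit",
    "RingSpacing",
    "ReconciliationReport",
    "parse_domain_table",
    "locate_ring_ligands",
    "classify_ring",
    "load_rule_table",
    "screen_proteome",
    "reconcile",
    "strip_isoform",
]

logger = logging.getLogger(__name__)

#: Member databases whose signatures count as RING evidence.
SIGNATURE_DBS = frozenset(
    {"Gene3D", "SUPERFAMILY", "ProSiteProfiles", "SMART", "Pfam",
     "ProSitePatterns"}
)

#: Reason codes accepted when a previously listed gene drops out.
DROP_REASONS = frozenset(
    {"merged", "no-RING-domain", "absent-from-db", "pseudogene",
     "split-new-locus", "transposable-element"}
)


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    signature_db: str
    signature_accession: str
    start: int  # 1-based inclusive
    end: int

    @property
    def in_scope(self) -> bool:
        return self.signature_db in SIGNATURE_DBS


@dataclass
class RingDomainHit:
    protein_id: str
    span: tuple[int, int]  # 1-based inclusive
    ligand_positions: tuple[int, ...]  # 8 positions, 1-based
    ligand_residues: tuple[str, ...]
    ring_class: str


@dataclass
class RingSpacing:
    """Spacing bounds and allowed residues of the canonical RING consensus.

    ``gaps`` are the (min, max) number of residues between consecutive
    ligands; ``allowed`` gives the permitted residue set per ligand
    position (1-based).  These are configuration, not constants — revised
    consensus definitions can be dropped in.
    """

    gaps: tuple[tuple[int, int], ...] = (
        (2, 2), (9, 39), (1, 3), (2, 3), (2, 2), (4, 48), (2, 2),
    )
    allowed: tuple[frozenset, ...] = (
        frozenset("C"), frozenset("C"), frozenset("C"),
        frozenset("CHDST"), frozenset("CHDST"),
        frozenset("C"), frozenset("C"), frozenset("C"),
    )


DEFAULT_SPACING = RingSpacing()


def parse_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read an InterProScan tabular output file.

    Expects the standard ≥11-column TSV (protein accession, MD5, length,
    analysis, signature accession, description, start, end, score, status,
    date, ...).  Malformed rows are skipped with a logged line number;
    rows from databases outside the six in-scope ones are kept but
    flagged via :attr:`DomainAnnotation.in_scope`.
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                logger.warning("line %d: %d columns (<11), skipped",
                               lineno, len(fields))
                continue
            try:
                start, end = int(fields[6]), int(fields[7])
            except ValueError:
                logger.warning("line %d: non-integer span, skipped", lineno)
                continue
            if not 1 <= start <= end:
                logger.warning("line %d: invalid span %d..%d, skipped",
                               lineno, start, end)
                continue
            ann = DomainAnnotation(
                protein_id=fields[0],
                signature_db=fields[3],
                signature_accession=fields[4],
                start=start,
                end=end,
            )
            if not ann.in_scope:
                logger.info("line %d: database %r outside signature scope",
                            lineno, ann.signature_db)
            annotations.append(ann)
    return annotations


def _candidates(seq: str, allowed: frozenset, lo: int, hi: int) -> list[int]:
    return [i for i in range(lo, min(hi + 1, len(seq))) if seq[i] in allowed]


def locate_ring_ligands(
    sequence: str,
    span: tuple[int, int] | None = None,
    spacing: RingSpacing = DEFAULT_SPACING,
) -> tuple[int, ...] | None:
    """Find the eight metal-ligand positions of a canonical RING domain.

    Searches ``sequence`` (optionally restricted to the 1-based inclusive
    ``span``) for residue positions obeying the consensus spacing.  When
    several placements exist the leftmost-longest wins: smallest first
    ligand position, then largest last ligand position, then the
    lexicographically smallest position tuple.  Returns 1-based positions
    or ``None`` when the protein is not canonical.
    """
    seq = sequence.upper()
    if span is None:
        lo, hi = 0, len(seq) - 1
    else:
        lo, hi = span[0] - 1, span[1] - 1
        if lo < 0 or hi >= len(seq) or lo > hi:
            raise ValueError(f"span {span} outside sequence of length {len(seq)}")
    sub = seq[lo:hi + 1]
    gaps, allowed = spacing.gaps, spacing.allowed

    best: tuple[int, ...] | None = None
    for p1 in range(len(sub)):
        if sub[p1] not in allowed[0]:
            continue
        if best is not None:
            break  # leftmost p1 already found and matched
        matches: list[tuple[int, ...]] = []
        stack = [(p1,)]
        while stack:
            partial = stack.pop()
            k = len(partial)
            if k == 8:
                matches.append(partial)
                continue
            g_lo, g_hi = gaps[k - 1]
            base = partial[-1]
            for q in range(base + g_lo + 1, min(base + g_hi + 2, len(sub))):
                if sub[q] in allowed[k]:
                    stack.append(partial + (q,))
        if matches:
            best = min(matches, key=lambda m: (-m[-1], m))
    if best is None:
        return None
    return tuple(p + lo + 1 for p in best)


def load_rule_table(path: str | Path | None = None) -> dict:
    """Load the RING subtype rule table (package default or a user file)."""
    if path is None:
        text = (
            resources.files("florascreen") / "data" / "ring_classes.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    for key in ("pair_classes", "substituent_classes", "fallback"):
        if key not in table:
            raise ValueError(f"rule table missing key {key!r}")
    return table


_DEFAULT_RULES = None


def classify_ring(
    ligand_residues: tuple[str, ...] | str,
    rules: dict | None = None,
) -> str:
    """RING subtype from the eight ligand residues.

    When positions 1, 2, 3, 6, 7, 8 are all cysteine the class is read
    from the (position 4, position 5) pair; otherwise a non-canonical
    substituent (D, S/T, G) at any metal position names the class, and
    anything else is ``non-canonical``.  Total on arbitrary residue
    8-tuples.
    """
    global _DEFAULT_RULES
    if rules is None:
        if _DEFAULT_RULES is None:
            _DEFAULT_RULES = load_rule_table()
        rules = _DEFAULT_RULES
    residues = tuple(str(r).upper() for r in ligand_residues)
    if len(residues) != 8:
        raise ValueError(f"need exactly 8 ligand residues, got {len(residues)}")
    rest = residues[:3] + residues[5:]
    if all(r == "C" for r in rest):
        key = f"{residues[3]},{residues[4]}"
        if key in rules["pair_classes"]:
            return rules["pair_classes"][key]
        for pos in (residues[3], residues[4]):
            if pos in rules["substituent_classes"]:
                return rules["substituent_classes"][pos]
        return rules["fallback"]
    for r in residues:
        if r in rules["substituent_classes"]:
            return rules["substituent_classes"][r]
    return rules["fallback"]


def screen_proteome(
    proteins: dict[str, str],
    annotations: list[DomainAnnotation],
    spacing: RingSpacing = DEFAULT_SPACING,
    rules: dict | None = None,
) -> tuple[list[RingDomainHit], list[str]]:
    """Locate and classify RING domains across a proteome.

    ``proteins`` maps protein id to sequence; ``annotations`` supply the
    candidate spans (only in-scope databases are used; any-hit rule —
    each protein's annotated spans are tried in order and the first
    successful ligand location wins).  Returns canonical hits plus the
    signature-only tier: proteins with an in-scope signature whose
    spacing could not be validated.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        if ann.in_scope and ann.protein_id in proteins:
            spans.setdefault(ann.protein_id, []).append((ann.start, ann.end))
    hits: list[RingDomainHit] = []
    signature_only: list[str] = []
    for pid in sorted(spans):
        seq = proteins[pid]
        found = None
        for span in sorted(spans[pid]):
            span = (max(1, span[0]), min(len(seq), span[1]))
            if span[0] > span[1]:
                continue
            pos = locate_ring_ligands(seq, span, spacing)
            if pos is not None:
                found = (span, pos)
                break
        if found is None:
            signature_only.append(pid)
            continue
        span, pos = found
        residues = tuple(seq[p - 1].upper() for p in pos)
        hits.append(RingDomainHit(
            protein_id=pid,
            span=span,
            ligand_positions=pos,
            ligand_residues=residues,
            ring_class=classify_ring(residues, rules),
        ))
    return hits, signature_only


def strip_isoform(protein_id: str) -> str:
    """Collapse an isoform accession (``AT1G12345.2``) to its locus."""
    return re.sub(r"\.\d+$", "", protein_id)


@dataclass
class ReconciliationReport:
    matched: set = field(default_factory=set)
    newly_identified: set = field(default_factory=set)
    dropped: dict = field(default_factory=dict)  # id -> reason
    unresolved: set = field(default_factory=set)

    @property
    def counts(self) -> dict[str, int]:
        summary: dict[str, int] = {
            "matched": len(self.matched),
            "newly_identified": len(self.newly_identified),
            "dropped": len(self.dropped) + len(self.unresolved),
        }
        for reason in sorted(set(self.dropped.values())):
            summary[reason] = sum(
                1 for r in self.dropped.values() if r == reason
            )
        if self.unresolved:
            summary["unresolved"] = len(self.unresolved)
        return summary


def reconcile(
    new_ids: set[str] | list[str],
    old_ids: set[str] | list[str],
    evidence: dict[str, str] | None = None,
) -> ReconciliationReport:
    """Partition a previous gene census against the current one.

    Isoform suffixes are stripped before set operations.  Old loci absent
    from the new set are dropped with the reason supplied in ``evidence``
    (one of the recognised codes) or listed as unresolved.
    """
    evidence = evidence or {}
    new = {strip_isoform(i) for i in new_ids}
    old = {strip_isoform(i) for i in old_ids}
    report = ReconciliationReport(
        matched=new & old,
        newly_identified=new - old,
    )
    for gene in sorted(old - new):
        reason = evidence.get(gene) or evidence.get(strip_isoform(gene))
        if reason is None:
            report.unresolved.add(gene)
        elif reason not in DROP_REASONS:
            raise ValueError(f"unknown drop reason {reason!r} for {gene}")
        else:
            report.dropped[gene] = reason
    return report
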