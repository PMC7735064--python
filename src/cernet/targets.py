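"""miRNA seed-match target prediction.

Scans transcript sequences (circRNA bodies or mRNA 3'UTRs) for exact
Watson-Crick complements of a miRNA seed and classifies hits into the
canonical site hierarchy:

* ``8mer``    — perfect match to miRNA positions 2-8 plus an adenosine on the
  target opposite miRNA position 1,
* ``7mer-m8`` — perfect match to positions 2-8,
* ``7mer-A1`` — match to positions 2-7 plus the opposite-position-1 A,
* ``6mer``    — match to positions 2-7 only.

Every 6mer-core hit is reported exactly once, under the most specific class
it satisfies, so the four classes partition the hits.  circRNAs are scanned
as circular sequences: the scan window wraps across the back-splice junction
and site coordinates are reported modulo the transcript length.

This is a seed-complementarity stand-in for alignment-based predictors
(miRanda-style thermodynamics are deliberately out of scope); externally
computed edge tables can be supplied to the network stages instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BindingSite",
    "TargetEdge",
    "SITE_WEIGHTS",
    "find_seed_sites",
    "scan_transcripts",
    "site_score",
    "score_and_rank",
    "shared_target_filter",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Weight of each site class in an edge's aggregate score.
SITE_WEIGHTS = {"8mer": 5, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}


@dataclass(frozen=True)
class BindingSite:
    """One seed-match site, 0-based half-open transcript coordinates.

    For sites wrapping a circular transcript's back-splice junction,
    ``start`` is reported modulo the transcript length and may exceed
    ``end``; ``end - start`` then differs from the physical site length,
    which is always given by ``length``.
    """

    transcript_id: str
    start: int
    end: int
    site_class: str
    length: int

    def __post_init__(self) -> None:
        if self.site_class not in SITE_WEIGHTS:
            raise ValueError(f"unknown site class {self.site_class!r}")


@dataclass
class TargetEdge:
    """A predicted miRNA->transcript interaction with its site evidence."""

    source: str  # miRNA id
    target: str  # transcript id
    sites: list[BindingSite] = field(default_factory=list)

    @property
    def score(self) -> int:
        return site_score(self.sites)


def _normalize(seq: str, name: str) -> str:
    """Uppercase, RNA->DNA (U->T); reject anything outside ACGUT."""
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch == "U":
            ch = "T"
        if ch not in _COMPLEMENT:
            raise ValueError(f"invalid character {ch!r} at position {i} of {name}")
        out.append(ch)
    return "".join(out)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def find_seed_sites(
    transcript: str,
    mirna: str,
    *,
    transcript_id: str = "",
    circular: bool = False,
) -> list[BindingSite]:
    """Find all seed-match sites for one miRNA on one transcript.

    The miRNA is given 5'->3'; its seed core is positions 2-7 (0-based
    ``mirna[1:7]``) and the m8 extension is position 8.  A site is any exact
    occurrence of the reverse complement of the core on the transcript
    (U and T are interchangeable on both sides).  With ``circular=True`` the
    transcript is treated as covalently closed: scanning continues across the
    junction and coordinates wrap.

    Returns sites ordered by start coordinate, one per distinct core start.
    """
    t = _normalize(transcript, "transcript")
    m = _normalize(mirna, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt to define a seed")
    n = len(t)
    core = m[1:7]
    site = _revcomp(core)  # 6 nt on the target, 5'->3'
    m8 = _COMPLEMENT[m[7]]  # target base pairing miRNA position 8

    # On the target (5'->3') a full site reads: [m8 base][core 6mer][A1 'A'];
    # circularity is handled by scanning with a 7-nt wrap-around pad.
    scan = t + t[: min(7, n)] if circular else t
    sites: list[BindingSite] = []
    for s in range(n if circular else max(n - 5, 0)):
        if scan[s : s + 6] != site:
            continue
        if not circular and s + 6 > n:
            continue
        has_m8 = (t[(s - 1) % n] == m8) if circular else (s >= 1 and t[s - 1] == m8)
        a1_pos = (s + 6) % n if circular else s + 6
        has_a1 = (a1_pos < n) and (t[a1_pos] == "A") if not circular else (t[a1_pos] == "A")
        if has_m8 and has_a1:
            cls, start, length = "8mer", s - 1, 8
        elif has_m8:
            cls, start, length = "7mer-m8", s - 1, 7
        elif has_a1:
            cls, start, length = "7mer-A1", s, 7
        else:
            cls, start, length = "6mer", s, 6
        start = start % n if circular else start
        end = (start + length) % n if circular else start + length
        if circular and end == 0:
            end = n
        sites.append(
            BindingSite(
                transcript_id=transcript_id,
                start=start,
                end=end,
                site_class=cls,
                length=length,
            )
        )
    return sites


def site_score(sites: list[BindingSite]) -> int:
    """Weighted site tally: 5*8mer + 3*7mer-m8 + 2*7mer-A1 + 1*6mer."""
    return sum(SITE_WEIGHTS[s.site_class] for s in sites)


def scan_transcripts(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    *,
    circular: bool = False,
) -> list[TargetEdge]:
    """All-vs-all seed scan; returns only edges with at least one site."""
    if len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    edges = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            sites = find_seed_sites(tseq, mseq, transcript_id=tid, circular=circular)
            if sites:
                edges.append(TargetEdge(source=mid, target=tid, sites=sites))
    return edges


def score_and_rank(
    edges: list[TargetEdge],
    top_k: int,
    *,
    group_by: str = "source",
) -> dict[str, list[TargetEdge]]:
    """Rank edges within each group and keep the top ``top_k``.

    ``group_by="source"`` ranks transcripts per miRNA; ``group_by="target"``
    ranks miRNAs per transcript (the per-circRNA top-k sponged miRNAs).
    Sort key: score descending, then partner id ascending.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if group_by not in ("source", "target"):
        raise ValueError("group_by must be 'source' or 'target'")
    seen: set[tuple[str, str]] = set()
    groups: dict[str, list[TargetEdge]] = {}
    for e in edges:
        key = (e.source, e.target)
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        groups.setdefault(getattr(e, group_by), []).append(e)
    other = "target" if group_by == "source" else "source"
    return {
        g: sorted(es, key=lambda e: (-e.score, getattr(e, other)))[:top_k]
        for g, es in sorted(groups.items())
    }


def shared_target_filter(
    top_lists: dict[str, list[str]],
    min_sources: int = 2,
) -> set[str]:
    """miRNAs appearing in the top-k lists of at least ``min_sources`` circRNAs."""
    if len(top_lists) < 2:
        raise ValueError("need at least two source circRNAs")
    counts: dict[str, int] = {}
    for mirnas in top_lists.values():
        for m in set(mirnas):
            counts[m] = counts.get(m, 0) + 1
    return {m for m, c in counts.items() if c >= min_sources}
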