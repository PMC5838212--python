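"""Canonical miRNA seed-site scanning on 3'-UTRs and site-disruption mutants.

A miRNA represses a transcript mainly through Watson-Crick pairing between
its seed (nucleotides 2-7 from the 5' end) and a complementary stretch of the
3'-UTR.  The canonical site taxonomy, from weakest to strongest:

* ``6mer``    — UTR matches the reverse complement of miRNA nt 2-7;
* ``7mer-A1`` — 6mer plus an adenosine opposite miRNA position 1;
* ``7mer-m8`` — UTR matches the reverse complement of miRNA nt 2-8;
* ``8mer``   — both the m8 match and the A1 adenosine.

At a given seed-core locus the longest applicable type subsumes the shorter
ones, so each core match yields exactly one reported site.  U and T are
equivalent; scanning is on the given (sense, 5'->3') UTR strand only.

:func:`disrupt_site` builds the 2-nt binding-site mutants used in reporter
assays: point transversions inside the seed core, verified (when the miRNA is
given) to abolish every site overlapping the original locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

__all__ = ["SeedSite", "seed_sites", "disrupt_site", "crossmatch", "clean_sequence"]


@dataclass(frozen=True)
class SeedSite:
    """A located seed match on a UTR (0-based, half-open, 5'->3')."""

    utr_id: str
    start: int
    end: int
    site_type: str
    mirna_id: str

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def clean_sequence(seq: str, what: str = "sequence") -> str:
    """Uppercase, U->T; reject ambiguity codes (no IUPAC wildcard matching)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT/U characters: {sorted(bad)}")
    return s


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def seed_sites(
    utr: str,
    mirna: str,
    mirna_id: str = "mirna",
    utr_id: str = "utr",
) -> list[SeedSite]:
    """All canonical seed sites for one miRNA on one UTR, 5'->3' order.

    The UTR hexamer matching the reverse complement of miRNA nt 2-7 anchors a
    candidate; the m8 extension (one more complementary base 5' of the
    hexamer) and the A1 adenosine (an ``A`` immediately 3' of it) upgrade the
    type, longest type wins.
    """
    u = clean_sequence(utr, "UTR")
    m = clean_sequence(mirna, "miRNA")
    if len(m) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    if len(u) < 6:
        return []
    core = _revcomp(m[1:7])  # pairs seed nt 2-7
    m8 = _COMPLEMENT[m[7]]  # UTR base pairing miRNA position 8
    sites = []
    pos = u.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and u[pos - 1] == m8
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(utr_id, pos - 1, pos + 7, "8mer", mirna_id)
        elif has_m8:
            site = SeedSite(utr_id, pos - 1, pos + 6, "7mer-m8", mirna_id)
        elif has_a1:
            site = SeedSite(utr_id, pos, pos + 7, "7mer-A1", mirna_id)
        else:
            site = SeedSite(utr_id, pos, pos + 6, "6mer", mirna_id)
        sites.append(site)
        pos = u.find(core, pos + 1)
    return sorted(sites, key=lambda s: (s.start, s.end))


def _core_span(site: SeedSite) -> tuple[int, int]:
    # seed-core hexamer coordinates within the site footprint
    if site.site_type in ("8mer", "7mer-m8"):
        return site.start + 1, site.start + 7
    return site.start, site.start + 6


def disrupt_site(
    utr: str,
    site: SeedSite,
    n_mut: int = 2,
    seed: int | None = None,
    mirna: str | None = None,
) -> str:
    """Mutate ``n_mut`` bases inside a seed site to abolish it.

    Substitutions are deterministic transversions (A<->C, G<->T) at seed-core
    positions chosen center-outward (or shuffled when ``seed`` is given).
    When the mature miRNA sequence is supplied the mutant is verified by
    rescanning: no site of any type may overlap the original footprint;
    alternative position subsets are tried until that holds.
    """
    u = clean_sequence(utr, "UTR")
    if not (0 <= site.start < site.end <= len(u)):
        raise ValueError("site does not lie within the UTR")
    width = site.end - site.start
    if n_mut > width:
        raise ValueError(f"n_mut={n_mut} exceeds site length {width}")
    if n_mut < 1:
        raise ValueError("n_mut must be >= 1")
    c0, c1 = _core_span(site)
    core_positions = list(range(c0, c1))
    mid = (c0 + c1 - 1) / 2
    core_positions.sort(key=lambda p: (abs(p - mid), p))  # center-outward
    extra = [p for p in range(site.start, site.end) if p not in core_positions]
    ordered = core_positions + extra
    if seed is not None:
        rng = np.random.default_rng(seed)
        ordered = list(rng.permutation(ordered))

    def mutate(positions: Sequence[int]) -> str:
        chars = list(u)
        for p in positions:
            chars[p] = _TRANSVERSION[chars[p]]
        return "".join(chars)

    candidates = itertools.chain(
        [ordered[:n_mut]], itertools.combinations(ordered, n_mut)
    )
    for positions in candidates:
        mutant = mutate(list(positions))
        if mirna is None:
            return mutant
        hits = [s for s in seed_sites(mutant, mirna) if s.overlaps(site.start, site.end)]
        if not hits:
            return mutant
    raise ValueError("could not abolish the site with the requested mutation count")


def crossmatch(
    utrs: Mapping[str, str],
    mirnas: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every (UTR, miRNA) pair; returns (site table, per-pair counts).

    Site table columns: ``utr_id``, ``mirna_id``, ``start``, ``end``,
    ``site_type``.  Counts table: one row per pair with ``n_sites``.
    """
    if not utrs or not mirnas:
        cols = ["utr_id", "mirna_id", "start", "end", "site_type"]
        return pd.DataFrame(columns=cols), pd.DataFrame(
            columns=["utr_id", "mirna_id", "n_sites"]
        )
    for name, mapping in (("UTR", utrs), ("miRNA", mirnas)):
        ids = list(mapping)
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate {name} ids")
    rows, counts = [], []
    for uid, useq in utrs.items():
        for mid, mseq in mirnas.items():
            hits = seed_sites(useq, mseq, mirna_id=mid, utr_id=uid)
            counts.append({"utr_id": uid, "mirna_id": mid, "n_sites": len(hits)})
            rows.extend(
                {
                    "utr_id": s.utr_id,
                    "mirna_id": s.mirna_id,
                    "start": s.start,
                    "end": s.end,
                    "site_type": s.site_type,
                }
                for s in hits
            )
    sites = pd.DataFrame(rows, columns=["utr_id", "mirna_id", "start", "end", "site_type"])
    return sites, pd.DataFrame(counts)
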