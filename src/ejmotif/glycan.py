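"""CFG glycan-microarray analysis: normalization, background filtering,
differential ranking, and structural interpretation of IUPAC-condensed
glycan strings.

The screen probes a mammalian glycan array with two synthetic eJM peptides
(JM-a and JM-b) at two amounts each; readout is relative fluorescence units
(RFU) per glycan with replicate spots.  Analysis steps: total-RFU
normalization per sample, background removal by CV%/RFU thresholds,
pseudolog2 fold-change ranking of JM-a over JM-b binding, and
Mann-Whitney enrichment of structural determinants (short residue-linkage
motifs such as ``GlcNAcb1-6``) among the high-affinity glycans.

Structures are parsed from IUPAC-condensed strings
(e.g. ``Galb1-4GlcNAcb1-2Mana1-6(...)Manb1-4GlcNAcb1-4GlcNAc-Asn``) into
rooted trees whose edges carry anomeric/linkage annotations; the reducing
end is the root.  Spacer suffixes (``-Sp0`` ...) are stripped; an ``-Asn``
suffix is kept as a root annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

#: The determinants considered in the enrichment analysis.
DETERMINANTS = (
    "Gala1-3", "Galb1-3", "Galb1-4",
    "GlcNAcb1-2", "GlcNAcb1-3", "GlcNAcb1-4", "GlcNAcb1-6",
    "GalNAca1-3", "GalNAcb1-4",
    "Neu5Aca2-3", "Neu5Aca2-6",
    "Mana1-3", "Manb1-4", "Mana1-6",
    "Fuca1-2", "Fuca1-3", "Fuca1-6",
)

# longest-first so GlcNAc wins over Glc, Neu5Gc over Neu, etc.
MONOSACCHARIDES = (
    "GlcNAc", "GalNAc", "ManNAc", "Neu5Ac", "Neu5Gc", "GlcA", "IdoA",
    "Glc", "Gal", "Man", "Fuc", "Xyl", "Rha", "Ara", "KDN", "Kdo",
)


class GlycanParseError(ValueError):
    """Raised with the offending position when a structure cannot be parsed."""


@dataclass
class Monosaccharide:
    """A node in a rooted glycan tree.

    ``anomeric``/``child_pos``/``parent_pos`` describe the linkage to the
    parent (e.g. b, 1, 4 for ``b1-4``); they are None on the root.
    """

    name: str
    anomeric: Optional[str] = None
    child_pos: Optional[str] = None
    parent_pos: Optional[str] = None
    children: List["Monosaccharide"] = field(default_factory=list)

    def linkage(self) -> Optional[str]:
        if self.anomeric is None:
            return None
        return f"{self.anomeric}{self.child_pos}-{self.parent_pos}"

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def __eq__(self, other):
        if not isinstance(other, Monosaccharide):
            return NotImplemented
        return (
            self.name == other.name
            and self.linkage() == other.linkage()
            and self.children == other.children
        )


@dataclass
class GlycanStructure:
    root: Monosaccharide
    suffix: Optional[str] = None  # "-Asn" retained; spacers stripped

    def walk(self):
        yield from self.root.walk()

    def __eq__(self, other):
        if not isinstance(other, GlycanStructure):
            return NotImplemented
        return self.root == other.root and self.suffix == other.suffix


_LINKAGE_RE = re.compile(r"([ab?])([12?])-([0-9?/]+)")
_SPACER_RE = re.compile(r"-Sp\w+$")


def _match_residue(s: str, pos: int) -> Tuple[str, int]:
    for name in MONOSACCHARIDES:
        if s.startswith(name, pos):
            return name, pos + len(name)
    raise GlycanParseError(
        f"unknown monosaccharide token at position {pos}: {s[pos:pos + 8]!r}"
    )


def parse_glycan(structure: str) -> GlycanStructure:
    """Parse an IUPAC-condensed glycan string into a rooted tree.

    The rightmost residue (reducing end) becomes the root; parenthesized
    segments are branches on the residue that follows them.
    """
    if not structure or not structure.strip():
        raise GlycanParseError("empty structure string")
    s = structure.strip()
    suffix = None
    if s.endswith("-Asn"):
        suffix, s = "-Asn", s[: -len("-Asn")]
    else:
        m = _SPACER_RE.search(s)
        if m:
            s = s[: m.start()]
    root, end = _parse_chain(s, 0, top=True)
    if end != len(s):
        raise GlycanParseError(f"unexpected trailing text at position {end}")
    return GlycanStructure(root=root, suffix=suffix)


def _parse_chain(s: str, pos: int, top: bool) -> Tuple[Monosaccharide, int]:
    """Parse residues/branches until the chain's terminal residue.

    In a top-level chain the terminal residue has no linkage (it is the
    root); inside parentheses the terminal residue keeps its linkage to the
    parent outside.
    """
    pending: List[Monosaccharide] = []
    while pos < len(s):
        if s[pos] == "(":
            depth, j = 1, pos + 1
            while j < len(s) and depth:
                if s[j] == "(":
                    depth += 1
                elif s[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise GlycanParseError(f"unbalanced parenthesis at position {pos}")
            branch, bend = _parse_chain(s[pos + 1 : j - 1], 0, top=False)
            if bend != j - 1 - (pos + 1):
                raise GlycanParseError(
                    f"unexpected text inside branch at position {pos + 1 + bend}"
                )
            if branch.anomeric is None:
                raise GlycanParseError(
                    f"branch ending at position {j} lacks a linkage"
                )
            pending.append(branch)
            pos = j
            continue
        name, pos2 = _match_residue(s, pos)
        m = _LINKAGE_RE.match(s, pos2)
        if m:
            node = Monosaccharide(
                name=name, anomeric=m.group(1), child_pos=m.group(2),
                parent_pos=m.group(3), children=pending,
            )
            pending = [node]
            pos = m.end()
            if pos == len(s):
                if top:
                    raise GlycanParseError(
                        "top-level chain ends with a dangling linkage"
                    )
                return node, pos
        else:
            # terminal residue of a top-level chain: the reducing-end root
            node = Monosaccharide(name=name, children=pending)
            return node, pos2
    raise GlycanParseError(f"unexpected end of string at position {pos}")


def serialize_glycan(structure: GlycanStructure) -> str:
    """Inverse of :func:`parse_glycan` (round-trips parser output)."""

    def _ser(node: Monosaccharide) -> str:
        parts = []
        for i, child in enumerate(node.children):
            text = _ser(child) + child.linkage()
            parts.append(text if i == 0 else f"({text})")
        return "".join(parts) + node.name

    return _ser(structure.root) + (structure.suffix or "")


def has_determinant(structure: GlycanStructure, determinant: str) -> bool:
    """True iff some edge matches the determinant's residue + linkage."""
    if determinant not in DETERMINANTS:
        raise ValueError(f"unknown determinant: {determinant!r}")
    m = re.fullmatch(r"([A-Za-z5]+)([ab])([12])-([0-9]+)", determinant)
    name, anomeric, child_pos, parent_pos = m.groups()
    for node in structure.walk():
        if (
            node.name == name
            and node.anomeric == anomeric
            and node.child_pos == child_pos
            and node.parent_pos == parent_pos
        ):
            return True
    return False


def _nglycan_core(structure: GlycanStructure):
    """The (root GlcNAc, core GlcNAc, core Man, arm Mans) of an N-glycan
    core ``Mana1-3/6 on Manb1-4GlcNAcb1-4GlcNAc``, or None."""
    root = structure.root
    if root.name != "GlcNAc":
        return None
    core_glcnac = next(
        (c for c in root.children
         if c.name == "GlcNAc" and c.linkage() == "b1-4"),
        None,
    )
    if core_glcnac is None:
        return None
    core_man = next(
        (c for c in core_glcnac.children
         if c.name == "Man" and c.linkage() == "b1-4"),
        None,
    )
    if core_man is None:
        return None
    arms = [
        c for c in core_man.children
        if c.name == "Man" and c.anomeric == "a" and c.parent_pos in ("3", "6")
    ]
    if {a.parent_pos for a in arms} != {"3", "6"}:
        return None
    return root, core_glcnac, core_man, arms


def is_nglycan(structure: GlycanStructure) -> bool:
    """True iff the structure carries the trimannosyl-chitobiose N-core."""
    return _nglycan_core(structure) is not None


def is_complex_nglycan(structure: GlycanStructure) -> bool:
    """True iff the N-glycan core carries >= 1 GlcNAc-initiated antenna.

    Complex N-glycans extend the Man3GlcNAc2 core with antennae that begin
    with a GlcNAc on a core-arm mannose (GlcNAcb1-2/4/6-Man); high-mannose
    structures (mannose-only antennae) and non-N-glycans return False.
    """
    core = _nglycan_core(structure)
    if core is None:
        return False
    _, _, _, arms = core
    for arm in arms:
        for c in arm.children:
            if c.name == "GlcNAc" and c.anomeric == "b" and c.parent_pos in (
                "2", "4", "6",
            ):
                return True
    return False


def total_rfu_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample column by its total RFU, keeping RFU magnitude.

    Every sample column is divided by its column total and rescaled by the
    grand mean of the sample totals, so normalized values stay on an
    RFU-like scale while total signal per sample is equalized.
    """
    values = table.astype(float)
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total RFU")
    return values / totals * totals.mean()


def background_filter(rfu, cv_percent, rfu_floor: float = 50.0,
                      cv_ceiling: float = 50.0, rule: str = "or"):
    """Keep-mask for array values; the complement is background.

    Default rule drops a value iff CV% > 50 *or* RFU < 50 (strict
    inequalities, per the "over"/"under" wording); ``rule="and"`` requires
    both.  NaN in either input is treated as background.
    """
    rfu = np.asarray(rfu, dtype=float)
    cv = np.asarray(cv_percent, dtype=float)
    noisy = cv > cv_ceiling
    dim = rfu < rfu_floor
    if rule == "or":
        drop = noisy | dim
    elif rule == "and":
        drop = noisy & dim
    else:
        raise ValueError("rule must be 'or' or 'and'")
    drop |= ~np.isfinite(rfu) | ~np.isfinite(cv)
    return ~drop


def pseudolog2_fc(rfu_a, rfu_b, pseudocount: float = 1.0):
    """log2((a + c) / (b + c)) on nonnegative RFUs."""
    a = np.asarray(rfu_a, dtype=float)
    b = np.asarray(rfu_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("RFU values must be nonnegative")
    out = np.log2(a + pseudocount) - np.log2(b + pseudocount)
    return float(out) if out.ndim == 0 else out


def rank_top_differential(fold_changes: pd.Series, k: int = 18) -> pd.Series:
    """Top-k glycans by descending fold change, ties by id (lexicographic)."""
    if k > fold_changes.size:
        raise ValueError("k exceeds the number of retained glycans")
    ordered = fold_changes.sort_index().sort_values(
        ascending=False, kind="stable"
    )
    return ordered.iloc[:k]


def recompute_cv(replicates: np.ndarray) -> np.ndarray:
    """Percent coefficient of variation across replicate axis (last)."""
    reps = np.asarray(replicates, dtype=float)
    mean = reps.mean(axis=-1)
    sd = reps.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, 100.0 * sd / mean, np.inf)


def determinant_enrichment(
    table: pd.DataFrame,
    determinants=DETERMINANTS,
    affinity_split: float = 1.5,
    rfu_a_col: str = "rfu_a",
    rfu_b_col: str = "rfu_b",
    structure_col: str = "structure",
) -> pd.DataFrame:
    """Mann-Whitney enrichment of structure determinants among high-affinity
    N-glycans.

    Glycans are N-glycans retained by the background filter; the reference
    group holds glycans with less than ``affinity_split`` x more JM-a than
    JM-b binding (rfu_a < 1.5 rfu_b), the comparison group the
    determinant-bearing glycans among the rest.  Normalized JM-a RFUs are
    compared two-sided (exact for combined n <= 20, otherwise the
    tie-corrected normal approximation with continuity correction); BH
    adjustment spans the determinant family.
    """
    parsed = []
    for _, row in table.iterrows():
        try:
            parsed.append(parse_glycan(row[structure_col]))
        except GlycanParseError:
            parsed.append(None)
    keep = [p is not None and is_nglycan(p) for p in parsed]
    sub = table[keep].copy()
    sub_parsed = [p for p, k in zip(parsed, keep) if k]

    high = sub[rfu_a_col].values >= affinity_split * sub[rfu_b_col].values
    ref_values = sub.loc[~high, rfu_a_col].values
    rows = []
    for det in determinants:
        has = np.array([has_determinant(p, det) for p in sub_parsed])
        grp_values = sub.loc[high & has, rfu_a_col].values
        if grp_values.size == 0 or ref_values.size == 0:
            rows.append({"determinant": det, "n_group": int(grp_values.size),
                         "p_raw": np.nan, "direction": "n/a"})
            continue
        method = "exact" if grp_values.size + ref_values.size <= 20 else "asymptotic"
        res = stats.mannwhitneyu(
            grp_values, ref_values, alternative="two-sided", method=method
        )
        direction = "up" if np.median(grp_values) >= np.median(ref_values) else "down"
        rows.append({"determinant": det, "n_group": int(grp_values.size),
                     "p_raw": float(res.pvalue), "direction": direction})
    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_raw"].values)
    return out
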