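"""Sliding-window eJM sequence-motif model for receptor tyrosine kinases.

Single-pass receptor tyrosine kinases (RTKs) carry a short extracellular
juxtamembrane (eJM) stretch — operationally the 30 residues upstream of the
transmembrane helix — that separates receptors into two functional classes:
those with a JM-a-like motif (selective STAT5a activators) and those without
it (JM-b-like, selective STAT5b activators).  The motif is modelled as a pair
of 6-residue reference windows taken from the ErbB4 JM-a and JM-b isoforms
(residues 627-632, ``GPTSHD`` and ``GSSIED``), scored against candidate
windows with PAM250 substitution scores under sparse position weightings.
The biochemical reading of the motif is a hydrogen-bond donor residue beside
an acceptor residue, three to four residues from a glycine — hence the two
admissible binary weightings over window positions {1,4,5} and {1,5,6}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WINDOW = 6

#: ErbB4 JM-a residues 627-632 (G627, P628, T629, S630, H631, D632).
JM_A_REFERENCE = "GPTSHD"
#: ErbB4 JM-b residues 627-632 (G627, S628, S629, I630, E631, D632).
JM_B_REFERENCE = "GSSIED"


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20 canonical residues."""


class ShapeError(ValueError):
    """A sequence or window has an inadmissible length."""


def _check_sequence(seq: str, min_len: int = WINDOW) -> str:
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise AlphabetError(f"non-canonical residue(s): {sorted(bad)}")
    if len(seq) < min_len:
        raise ShapeError(f"sequence length {len(seq)} < {min_len}")
    return seq


@dataclass(frozen=True)
class EjmSequence:
    """A receptor's membrane-proximal extracellular 30-mer (length >= 6)."""

    rtk_id: str
    sequence: str
    species: str = "human"
    tm_start: Optional[int] = None  # 1-based index in the parent sequence

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))

    def __len__(self):
        return len(self.sequence)


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp, count=len(seq))


class SubstitutionMatrix:
    """Symmetric residue-pair scores; defaults to PAM250."""

    def __init__(self, name: str = "PAM250", scores=None):
        self.name = name
        if scores is None:
            scores = substitution_matrices.load(name)
        self._scores = scores
        self._array = None

    def score(self, a: str, b: str) -> float:
        try:
            return float(self._scores[a, b])
        except (KeyError, IndexError) as exc:
            raise AlphabetError(f"no substitution score for pair ({a},{b})") from exc

    def as_array(self) -> np.ndarray:
        """20x20 score array indexed by the canonical alphabet order."""
        if self._array is None:
            arr = np.empty((20, 20))
            for i, a in enumerate(AMINO_ACIDS):
                for j, b in enumerate(AMINO_ACIDS):
                    arr[i, j] = self.score(a, b)
            self._array = arr
        return self._array


@dataclass(frozen=True)
class PositionWeighting:
    """Nonnegative weights over the six window positions (1-based)."""

    weights: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) != WINDOW:
            raise ShapeError(f"weighting must have {WINDOW} entries")
        if any(x < 0 for x in w):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_positions(cls, positions: Sequence[int]) -> "PositionWeighting":
        """Binary weighting from 1-based positions, e.g. (1, 5, 6)."""
        w = [0.0] * WINDOW
        for p in positions:
            w[p - 1] = 1.0
        return cls(tuple(w))

    @property
    def positions(self):
        return tuple(i + 1 for i, x in enumerate(self.weights) if x > 0)


@dataclass
class MotifModel:
    """Two reference windows, a substitution matrix, alternative weightings.

    The default is the final published model: JM-a/JM-b ErbB4 627-632
    references, PAM250, and the two binary weightings {1,4,5} and {1,5,6}.
    """

    jm_a_reference: str = JM_A_REFERENCE
    jm_b_reference: str = JM_B_REFERENCE
    weightings: tuple = field(
        default_factory=lambda: (
            PositionWeighting.from_positions((1, 4, 5)),
            PositionWeighting.from_positions((1, 5, 6)),
        )
    )
    matrix: SubstitutionMatrix = field(default_factory=SubstitutionMatrix)

    def __post_init__(self):
        for ref in (self.jm_a_reference, self.jm_b_reference):
            if len(_check_sequence(ref, WINDOW)) != WINDOW:
                raise ShapeError("reference windows must have length 6")
        if not self.weightings:
            raise ValueError("at least one position weighting is required")


@dataclass(frozen=True)
class ClassificationResult:
    rtk_id: str
    score_a: float
    score_b: float
    best_offset_a: int
    best_offset_b: int
    predicted_class: str  # "JM-a-like" or "JM-b-like"


def window_similarity(
    window: str,
    reference: str,
    weighting: PositionWeighting,
    matrix: SubstitutionMatrix,
) -> float:
    """Position-weighted substitution score of a 6-mer against a reference.

    Returns sum_i w_i * S(window_i, reference_i).
    """
    window = _check_sequence(window)
    reference = _check_sequence(reference)
    if len(window) != WINDOW or len(reference) != WINDOW:
        raise ShapeError("window and reference must both have length 6")
    return float(
        sum(
            w * matrix.score(a, b)
            for w, a, b in zip(weighting.weights, window, reference)
            if w != 0.0
        )
    )


def best_window_score(
    seq,
    reference: str,
    weighting: PositionWeighting,
    matrix: SubstitutionMatrix,
):
    """Maximum window_similarity over all contiguous 6-mers of *seq*.

    Returns ``(score, offset)`` with the smallest 0-based offset attaining
    the maximum.
    """
    s = seq.sequence if isinstance(seq, EjmSequence) else _check_sequence(seq)
    scores = _all_window_scores(
        _encode(s), _encode(_check_sequence(reference)), weighting, matrix
    )
    best_off = int(np.argmax(scores))  # argmax returns the smallest tied index
    return float(scores[best_off]), best_off


def _all_window_scores(
    codes: np.ndarray,
    ref_codes: np.ndarray,
    weighting: PositionWeighting,
    matrix: SubstitutionMatrix,
) -> np.ndarray:
    """Vectorized window scores at every 0-based offset of an encoded sequence."""
    arr = matrix.as_array()
    n_off = codes.size - WINDOW + 1
    scores = np.zeros(n_off)
    for i, w in enumerate(weighting.weights):
        if w != 0.0:
            scores += w * arr[codes[i : i + n_off], ref_codes[i]]
    return scores


def _motif_score(seq, reference: str, model: MotifModel):
    """Max over the model's weightings of the best window score."""
    best, best_off = -np.inf, 0
    for w in model.weightings:
        sc, off = best_window_score(seq, reference, w, model.matrix)
        if sc > best:
            best, best_off = sc, off
    return best, best_off


def classify_ejm(seq, model: Optional[MotifModel] = None) -> ClassificationResult:
    """Assign an eJM sequence to the JM-a-like or JM-b-like class.

    The class with the larger motif score wins; a tie is resolved to
    JM-b-like, reading the JM-b motif as the *absence* of a JM-a motif.
    """
    if model is None:
        model = MotifModel()
    if isinstance(seq, str):
        seq = EjmSequence(rtk_id="query", sequence=seq)
    score_a, off_a = _motif_score(seq, model.jm_a_reference, model)
    score_b, off_b = _motif_score(seq, model.jm_b_reference, model)
    predicted = "JM-a-like" if score_a > score_b else "JM-b-like"
    return ClassificationResult(
        rtk_id=seq.rtk_id,
        score_a=score_a,
        score_b=score_b,
        best_offset_a=off_a,
        best_offset_b=off_b,
        predicted_class=predicted,
    )


CLASS_LABELS = {"A": "JM-a-like", "B": "JM-b-like"}


def select_model(candidates, labeled_panel):
    """Evaluate candidate motif models on a labelled eJM panel.

    Parameters
    ----------
    candidates : sequence of MotifModel
    labeled_panel : sequence of (EjmSequence, label) with label in
        {"A", "B", "JM-a-like", "JM-b-like"}.

    Returns
    -------
    list of dict with keys ``model``, ``accuracy``, ``perfect``, sorted by
    accuracy descending (stable among ties).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    panel = [(s, CLASS_LABELS.get(lab, lab)) for s, lab in labeled_panel]
    if not panel:
        raise ValueError("empty panel")
    classes = {lab for _, lab in panel}
    if classes != {"JM-a-like", "JM-b-like"}:
        raise ValueError("panel must contain both classes")
    results = []
    for model in candidates:
        correct = sum(
            classify_ejm(s, model).predicted_class == lab for s, lab in panel
        )
        acc = correct / len(panel)
        results.append({"model": model, "accuracy": acc, "perfect": acc == 1.0})
    results.sort(key=lambda r: -r["accuracy"])  # stable
    return results


def binomial_categorization_pvalue(k_correct: int, n_total: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 0.5): chance-level categorization test."""
    if n_total < 1 or k_correct < 0 or k_correct > n_total:
        raise ValueError("require 0 <= k <= n and n >= 1")
    return float(stats.binom.sf(k_correct - 1, n_total, 0.5))


def extract_ejm(full_sequence: str, tm_start: int, length: int = 30) -> str:
    """The *length* residues immediately upstream of a 1-based TM start."""
    if tm_start is None:
        raise ValueError("tm_start annotation is required")
    if tm_start <= length:
        raise ShapeError(f"tm_start must exceed {length}")
    return full_sequence[tm_start - 1 - length : tm_start - 1]


def ejm_enrichment(
    full_sequences,
    model: Optional[MotifModel] = None,
    n_perm: int = 1000,
    seed: int = 0,
    reference: str = "A",
):
    """Permutation test for motif enrichment in eJM regions of receptors.

    For every receptor the JM-a (or JM-b) motif score of its 30-residue eJM
    window is ranked against the scores of *n_perm* equal-length windows
    sampled uniformly without replacement from the remainder of the
    ectodomain.  The statistic is the mean (across receptors) exceedance of
    the eJM window over its sampled windows; the one-sided p-value compares
    it with the statistics obtained by letting each sampled window play the
    observed role, with the (1 + hits) / (n_perm + 1) convention.

    Parameters
    ----------
    full_sequences : sequence of (ectodomain sequence, tm_start)
    reference : "A" or "B", which motif to test for enrichment.
    """
    if model is None:
        model = MotifModel()
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ref = model.jm_a_reference if reference == "A" else model.jm_b_reference
    rng = np.random.default_rng(seed)
    length = 30
    obs_exceed = []
    null_scores = []  # receptors x n_perm
    ref_codes = _encode(_check_sequence(ref))
    for seq, tm_start in full_sequences:
        seq = _check_sequence(seq, length + 1)
        ejm = extract_ejm(seq, tm_start, length)
        e_score, _ = _motif_score(
            EjmSequence(rtk_id="_", sequence=ejm), ref, model
        )
        ecto = seq[: tm_start - 1 - length]  # ectodomain upstream of the eJM
        n_off = len(ecto) - length + 1
        if n_off <= 0:
            raise ShapeError("ectodomain too short to sample null windows")
        codes = _encode(ecto)
        # motif score of the 30-mer starting at each ectodomain offset
        per_w = [
            _all_window_scores(codes, ref_codes, w, model.matrix)
            for w in model.weightings
        ]
        win_max = np.max(per_w, axis=0)
        # sliding maximum over the 25 window positions inside each 30-mer
        from numpy.lib.stride_tricks import sliding_window_view

        inner = length - WINDOW + 1
        offset_scores = sliding_window_view(win_max, inner).max(axis=1)[:n_off]
        replace = n_off < n_perm
        chosen = rng.choice(n_off, size=n_perm, replace=replace)
        scores = offset_scores[chosen]
        null_scores.append(scores)
        obs_exceed.append(np.mean(scores < e_score) + 0.5 * np.mean(scores == e_score))
    null_scores = np.array(null_scores)
    observed = float(np.mean(obs_exceed))
    # each sampled column acts as a pseudo-observation against its own panel
    n_rec = null_scores.shape[0]
    less = null_scores[:, :, None] < null_scores[:, None, :]
    ties = null_scores[:, :, None] == null_scores[:, None, :]
    exceed = less.mean(axis=2) + 0.5 * ties.mean(axis=2)  # receptors x n_perm
    null_stats = exceed.mean(axis=0)
    p = (1.0 + np.sum(null_stats >= observed)) / (n_perm + 1.0)
    return observed, float(p)


def conservation_similarity(
    motif_regions,
    reference: str,
    ortholog_ectodomains=None,
    n_draws: int = 10000,
    seed: int = 0,
):
    """Percent identity of per-taxon motif regions against a reference.

    Returns ``(mean, sd, p)`` where mean/sd are over taxa (sample sd) and the
    permutation p compares the observed mean identity with means obtained by
    drawing random equal-length windows from the provided ortholog
    ectodomains (``p is None`` when no ectodomains are supplied).
    """
    reference = _check_sequence(reference, 1)
    ids = []
    for region in motif_regions:
        region = _check_sequence(region, 1)
        if len(region) != len(reference):
            raise ShapeError("motif region length must match the reference")
        matches = sum(a == b for a, b in zip(region, reference))
        ids.append(100.0 * matches / len(reference))
    ids = np.asarray(ids)
    mean = float(ids.mean())
    sd = float(ids.std(ddof=1)) if ids.size > 1 else 0.0
    if ortholog_ectodomains is None:
        return mean, sd, None
    rng = np.random.default_rng(seed)
    L = len(reference)
    ectos = [_check_sequence(e, L) for e in ortholog_ectodomains]
    null_means = np.empty(n_draws)
    for b in range(n_draws):
        vals = []
        for e in ectos:
            off = rng.integers(0, len(e) - L + 1)
            win = e[off : off + L]
            vals.append(
                100.0 * sum(a == c for a, c in zip(win, reference)) / L
            )
        null_means[b] = np.mean(vals)
    p = (1.0 + np.sum(null_means >= mean)) / (n_draws + 1.0)
    return mean, sd, float(p)
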