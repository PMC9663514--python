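"""Synthetic-data generators with known ground truth for every pipeline
stage: labelled eJM panels, zero-inflated LFQ tables with spiked
interactors, glycan-array screens with determinant-linked effects,
two-channel punctae images with a controllable shared fraction, and
ortholog motif panels at a target identity.

Every generator is a pure function of its arguments: the same seed yields
byte-identical output, and each returns the ground truth needed to score
downstream callers (recall, FDR, bias) without re-derivation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .motif import AMINO_ACIDS, JM_A_REFERENCE, JM_B_REFERENCE, EjmSequence

_AA = np.array(list(AMINO_ACIDS))


def _mutate(seq: str, rate: float, rng) -> str:
    """Per-position substitution at the given rate, always to a different
    residue."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def gen_ejm_panel(n_per_class: int, mutation_rate: float = 0.0, seed: int = 0,
                  length: int = 30):
    """Labelled eJM panel with planted class reference windows.

    Each sequence is a uniform random *length*-mer with the class reference
    window (JM-a or JM-b, 6 residues) planted at a random offset, followed
    by per-position mutation at ``mutation_rate``.

    Returns ``(sequences, truth)`` where truth is a DataFrame with columns
    rtk_id, true_class ("A"/"B"), offset.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs, rows = [], []
    for label, ref in (("A", JM_A_REFERENCE), ("B", JM_B_REFERENCE)):
        for i in range(n_per_class):
            backbone = "".join(rng.choice(_AA, size=length))
            off = int(rng.integers(0, length - len(ref) + 1))
            planted = backbone[:off] + ref + backbone[off + len(ref):]
            mutated = _mutate(planted, mutation_rate, rng)
            rtk_id = f"SYN_{label}{i:03d}"
            seqs.append(EjmSequence(rtk_id=rtk_id, sequence=mutated,
                                    species="synthetic"))
            rows.append({"rtk_id": rtk_id, "true_class": label, "offset": off})
    return seqs, pd.DataFrame(rows)


def gen_lfq_table(
    n_proteins: int = 200,
    n_spiked: int = 10,
    spike_fold: float = 8.0,
    pi_zero: float = 0.3,
    n_experiments: int = 3,
    n_samples_per_condition: int = 2,
    n_fractions: int = 3,
    seed: int = 0,
    bait_condition: str = "bait_A",
    log2_mu: float = 20.0,
    log2_sigma: float = 1.5,
):
    """Zero-inflated log-normal LFQ table with bait-specific spiked preys.

    Background intensities are log-normal (2**N(log2_mu, log2_sigma), the
    LFQ magnitude regime), drawn independently per measurement — the
    generator does not model persistent per-protein abundance across
    samples.  Every measurement is zeroed (not detected) with probability
    ``pi_zero``; the first ``n_spiked`` proteins are multiplied by
    ``spike_fold`` in bait samples only.

    Returns ``(table, truth)``: a long-format DataFrame with columns
    protein_id, experiment, sample, fraction, condition, intensity, and a
    truth DataFrame flagging spiked proteins.
    """
    if n_spiked > n_proteins:
        raise ValueError("n_spiked must not exceed n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    spiked = set(proteins[:n_spiked])
    rows = []
    for e in range(n_experiments):
        for cond in ("vector_control", bait_condition):
            for s in range(n_samples_per_condition):
                sample = f"exp{e}_{cond}_s{s}"
                for f in range(n_fractions):
                    vals = 2.0 ** rng.normal(log2_mu, log2_sigma, n_proteins)
                    if cond == bait_condition:
                        vals = vals * np.where(
                            np.isin(proteins, list(spiked)), spike_fold, 1.0
                        )
                    vals = np.where(
                        rng.random(n_proteins) < pi_zero, 0.0, vals
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "protein_id": proteins,
                                "experiment": f"exp{e}",
                                "sample": sample,
                                "fraction": f"f{f}",
                                "condition": cond,
                                "intensity": vals,
                            }
                        )
                    )
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {"protein_id": proteins, "spiked": [p in spiked for p in proteins]}
    )
    return table, truth


# -- glycan grammar ---------------------------------------------------------

_ANTENNA_LINKS = ("2", "4", "6")


def _sample_structure(rng) -> str:
    """One IUPAC-condensed structure: complex N-glycan, high-mannose, or a
    short O-glycan-like chain."""
    kind = rng.choice(["complex", "highman", "short"], p=[0.5, 0.2, 0.3])
    if kind == "short":
        chains = [
            "Galb1-4Glc",
            "Galb1-3GalNAc",
            "Neu5Aca2-3Galb1-4GlcNAc",
            "Fuca1-2Galb1-3GalNAc",
            "GalNAca1-3Galb1-4GlcNAc",
            "Neu5Aca2-6Galb1-3GalNAc",
        ]
        return chains[rng.integers(len(chains))]
    core = "Manb1-4GlcNAcb1-4GlcNAc"
    if kind == "highman":
        arm3 = "Mana1-3"
        arm6 = "Mana1-6(Mana1-3)Mana1-6"
        if rng.random() < 0.5:
            arm3 = "Mana1-2Mana1-3"
        return f"{arm6}({arm3}){core}"

    def antenna() -> str:
        link = _ANTENNA_LINKS[rng.integers(3)]
        ant = f"GlcNAcb1-{link}"
        r = rng.random()
        if r < 0.4:
            ant = "Galb1-4" + ant
            if rng.random() < 0.5:
                ant = ("Neu5Aca2-6" if rng.random() < 0.5 else "Neu5Aca2-3") + ant
        elif r < 0.6:
            ant = "GalNAcb1-4" + ant
        return ant

    arm6 = antenna() + "Mana1-6"
    arm3 = antenna() + "Mana1-3"
    s = f"{arm6}({arm3}){core}"
    if rng.random() < 0.3:
        s = s[: -len("GlcNAc")] + "(Fuca1-6)GlcNAc"
    if rng.random() < 0.5:
        s += "-Asn"
    return s


def gen_glycan_table(
    n_glycans: int = 120,
    determinant_effects: dict | None = None,
    replicate_cv: float = 0.15,
    n_replicates: int = 4,
    base_log2_mu: float = 7.0,
    base_log2_sigma: float = 1.0,
    seed: int = 0,
):
    """Glycan-array screen with determinant-linked JM-a binding effects.

    Structures are drawn from a small grammar over complex N-glycans,
    high-mannose glycans and short O-glycan-like chains.  JM-a RFU is the
    baseline multiplied by the effect of every determinant present
    (``determinant_effects``: determinant -> multiplicative shift); JM-b
    RFU stays at baseline.  Replicates are drawn at ``replicate_cv``.

    Returns ``(table, truth)``; the table holds glycan_id, structure,
    per-replicate RFU columns, mean RFUs and recomputed CV%.
    """
    from .glycan import DETERMINANTS, has_determinant, parse_glycan, recompute_cv

    effects = determinant_effects or {}
    unknown = set(effects) - set(DETERMINANTS)
    if unknown:
        raise ValueError(f"unknown determinants: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n_glycans):
        structure = _sample_structure(rng)
        parsed = parse_glycan(structure)
        base = 2.0 ** rng.normal(base_log2_mu, base_log2_sigma)
        effect = 1.0
        present = []
        for det, mult in effects.items():
            if has_determinant(parsed, det):
                effect *= mult
                present.append(det)
        mu_a, mu_b = base * effect, base
        reps_a = np.abs(rng.normal(mu_a, replicate_cv * mu_a, n_replicates))
        reps_b = np.abs(rng.normal(mu_b, replicate_cv * mu_b, n_replicates))
        row = {"glycan_id": f"G{i:04d}", "structure": structure}
        row.update({f"rfu_a_rep{r}": reps_a[r] for r in range(n_replicates)})
        row.update({f"rfu_b_rep{r}": reps_b[r] for r in range(n_replicates)})
        row["rfu_a"] = reps_a.mean()
        row["rfu_b"] = reps_b.mean()
        row["cv_a"] = float(recompute_cv(reps_a[None, :])[0])
        row["cv_b"] = float(recompute_cv(reps_b[None, :])[0])
        rows.append(row)
        truth_rows.append(
            {
                "glycan_id": f"G{i:04d}",
                "structure": structure,
                "effect": effect,
                "determinants_present": ";".join(present),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def gen_coloc_images(
    shape=(256, 256),
    n_punctae: int = 150,
    shared_fraction: float = 0.5,
    psf_sigma: float = 2.0,
    noise_sd: float = 0.0,
    amplitude: float = 1000.0,
    seed: int = 0,
):
    """Two-channel punctae field with a controllable shared fraction.

    A fraction of Gaussian spots is placed at identical positions in both
    channels, the rest independently; additive Gaussian noise is clipped at
    zero.  Returns ``(ch1, ch2, truth)`` with the spot coordinates.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * n_punctae))
    n_solo = n_punctae - n_shared

    def field(points):
        img = np.zeros(shape)
        for r, c in points:
            img[r, c] += amplitude
        img = ndimage.gaussian_filter(img, psf_sigma)
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, shape)
        return np.clip(img, 0, None)

    def draw(n):
        return list(
            zip(
                rng.integers(0, shape[0], n),
                rng.integers(0, shape[1], n),
            )
        )

    shared = draw(n_shared)
    solo1, solo2 = draw(n_solo), draw(n_solo)
    ch1 = field(shared + solo1)
    ch2 = field(shared + solo2)
    truth = {"shared": shared, "solo1": solo1, "solo2": solo2}
    return ch1, ch2, truth


def gen_nuclei_image(shape=(256, 256), n_nuclei: int = 7, radius: int = 8,
                     amplitude: float = 100.0, seed: int = 0):
    """Disc nuclei on a dark background (non-overlapping grid placement)."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    margin = 2 * radius + 2
    cells_per_row = shape[1] // margin
    slots = rng.permutation(cells_per_row * (shape[0] // margin))[:n_nuclei]
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for slot in slots:
        r0 = (slot // cells_per_row) * margin + radius + 1
        c0 = (slot % cells_per_row) * margin + radius + 1
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = amplitude
    return img


def gen_ortholog_set(reference_region: str, n_taxa: int = 16,
                     target_identity: float = 0.85, seed: int = 0):
    """Per-taxon motif regions mutated from the reference.

    Each position mutates independently (to a different residue) with
    probability 1 - target_identity.
    """
    if not 0 <= target_identity <= 1:
        raise ValueError("target_identity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return [
        _mutate(reference_region, 1.0 - target_identity, rng)
        for _ in range(n_taxa)
    ]


def gen_feature_matrix(
    n_per_class: int = 6,
    n_features: int = 20,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Labelled bait x prey feature matrix with two planted clusters.

    Class centroids are ``separation * noise_sd`` apart along a random
    direction; rows are centroid + isotropic Gaussian noise.  With
    ``separation=0`` the labels carry no structure.
    """
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=n_features)
    direction /= np.linalg.norm(direction)
    shift = 0.5 * separation * noise_sd * direction
    X = np.vstack(
        [
            rng.normal(0, noise_sd, (n_per_class, n_features)) + shift,
            rng.normal(0, noise_sd, (n_per_class, n_features)) - shift,
        ]
    )
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y
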