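"""Curated ErbB4 eJM panels.

The ErbB4 JM-a / JM-b isoform pair is the model system for the eJM motif:
the isoforms differ at five residues between positions 626 and 631, and the
motif window is residues 627-632 (JM-a ``GPTSHD``, JM-b ``GSSIED``)
followed by ``CIYYPWT`` / ``CIGLMDR`` (residues 633-639).  The panels here
carry the motif region with its native flank, which is sufficient context
for the sliding-window classifier; full-length 30-mer eJM context can be
supplied by the caller when available.
"""

from __future__ import annotations

from typing import List, Tuple

from .motif import EjmSequence

#: ErbB4 JM-a residues 627-639.
ERBB4_JM_A_REGION = "GPTSHDCIYYPWT"
#: ErbB4 JM-b residues 627-639.
ERBB4_JM_B_REGION = "GSSIEDCIGLMDR"

_REGION_START = 627  # 1-based residue number of the first panel position


def _substitute(region: str, *muts: Tuple[int, str]) -> str:
    out = list(region)
    for pos, res in muts:
        out[pos - _REGION_START] = res
    return "".join(out)


def erbb4_isoform_panel() -> List[Tuple[EjmSequence, str]]:
    """The two wild-type ErbB4 isoform eJM motif regions with their
    experimentally established STAT5 classes."""
    return [
        (EjmSequence("ERBB4_JM-a", ERBB4_JM_A_REGION), "A"),
        (EjmSequence("ERBB4_JM-b", ERBB4_JM_B_REGION), "B"),
    ]


def erbb4_mutant_panel() -> List[Tuple[EjmSequence, str]]:
    """ErbB4 point mutants whose STAT5 activation outcome is a clean
    categorical call: motif-breaking JM-a mutants behave JM-b-like, and no
    tested JM-b mutant restores a JM-a motif.

    Partial/graded readouts (e.g. fold-change reductions without a class
    switch) are deliberately not represented here.
    """
    a, b = ERBB4_JM_A_REGION, ERBB4_JM_B_REGION
    panel = [
        (EjmSequence("ERBB4_JM-a_H631E", _substitute(a, (631, "E"))), "B"),
        (
            EjmSequence(
                "ERBB4_JM-a_S630I_H631E",
                _substitute(a, (630, "I"), (631, "E")),
            ),
            "B",
        ),
        (EjmSequence("ERBB4_JM-b_G627A", _substitute(b, (627, "A"))), "B"),
        (EjmSequence("ERBB4_JM-b_D632L", _substitute(b, (632, "L"))), "B"),
        (
            EjmSequence(
                "ERBB4_JM-b_E631D_D632L",
                _substitute(b, (631, "D"), (632, "L")),
            ),
            "B",
        ),
        (
            EjmSequence(
                "ERBB4_JM-b_E631Q_D632L",
                _substitute(b, (631, "Q"), (632, "L")),
            ),
            "B",
        ),
        (
            EjmSequence(
                "ERBB4_JM-b_E631N_D632L",
                _substitute(b, (631, "N"), (632, "L")),
            ),
            "B",
        ),
        (
            EjmSequence(
                "ERBB4_JM-b_E631L_D632L",
                _substitute(b, (631, "L"), (632, "L")),
            ),
            "B",
        ),
    ]
    return panel


def erbb4_motif_retaining_mutants() -> List[Tuple[EjmSequence, str]]:
    """JM-a substitutions that conserve the donor/acceptor pairing and keep
    STAT5a activation (donor swaps at 631, acceptor-compatible swaps at
    632, and the glycine-to-alanine change at 627)."""
    a = ERBB4_JM_A_REGION
    return [
        (EjmSequence(f"ERBB4_JM-a_{name}", _substitute(a, *muts)), "A")
        for name, muts in [
            ("G627A", ((627, "A"),)),
            ("H631R", ((631, "R"),)),
            ("H631Q", ((631, "Q"),)),
            ("H631N", ((631, "N"),)),
            ("D632E", ((632, "E"),)),
            ("D632Q", ((632, "Q"),)),
            ("D632N", ((632, "N"),)),
            ("D632H", ((632, "H"),)),
        ]
    ]


def validated_panel() -> List[Tuple[EjmSequence, str]]:
    """Isoforms plus all clean-call mutants (10 sequences, both classes)."""
    return erbb4_isoform_panel() + erbb4_mutant_panel()
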