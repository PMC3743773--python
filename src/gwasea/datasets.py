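"""Bundled example data: published summary tables from a dental caries
genome-wide association enrichment study (537 cases / 605 controls, 1,331 GO
terms of 5-250 genes, four enrichment methods).

Only printed summary numbers are bundled — per-method top-9 GO term lists
with raw p-values and annotated set sizes, and two contributing-gene lists —
enough to exercise the reporting layer (FDR replay, consensus combinatorics,
shared contributing genes) without any genotype-level data, which is
controlled-access.  Censored p-values printed as "<0.001" are replayed as
0.0005; they only ever enter through their ranks.
"""

from __future__ import annotations

import pandas as pd

#: number of gene sets each method tested (FDR denominators)
CARIES_N_SETS = 1331

#: display stand-in for p-values censored at the printing precision
CENSORED_P = 0.0005

# (term, annotated size, raw p, FDR) per method, in printed rank order
_TOP_TERMS: dict[str, list[tuple[str, int, float | str, float | str]]] = {
    "gengen": [
        ("Protein secretion", 32, "<0.001", "<0.001"),
        ("Cytokine secretion", 18, "<0.001", "<0.001"),
        ("Regulation of protein secretion", 22, "<0.001", "<0.001"),
        ("Regulation of cytokine secretion", 16, "<0.001", "<0.001"),
        ("Ligase activity forming carbon nitrogen bonds", 68, 0.001, 0.222),
        ("Positive regulation of protein secretion", 12, 0.001, 0.222),
        ("Rho guanyl nucleotide exchange factor activity", 11, 0.002, 0.380),
        ("Acid amino acid ligase activity", 57, 0.003, 0.499),
        ("Monocarboxylic acid transmembrane transporter activity", 11, 0.005, 0.666),
    ],
    "aligator": [
        ("Sphingoid metabolic process", 12, 0.004, 1.000),
        ("Transcription corepressor activity", 93, 0.008, 1.000),
        ("DNA helicase activity", 24, 0.009, 1.000),
        ("Ligase activity forming carbon nitrogen bonds", 68, 0.011, 1.000),
        ("Ubiquitin protein ligase activity", 49, 0.014, 1.000),
        ("Sensory perception", 188, 0.014, 1.000),
        ("Regulation of cytokine secretion", 16, 0.015, 1.000),
        ("ADP binding", 11, 0.015, 1.000),
        ("Ceramide metabolic process", 11, 0.017, 1.000),
    ],
    "srt": [
        ("Sphingoid metabolic process", 12, 0.001, 0.266),
        ("Neuropeptide receptor activity", 21, 0.001, 0.266),
        ("Neuropeptide binding", 22, 0.001, 0.266),
        ("Translation initiation factor activity", 23, 0.001, 0.266),
        ("Small protein conjugating enzyme activity", 52, 0.002, 0.266),
        ("Ceramide metabolic process", 11, 0.002, 0.266),
        ("Peptide receptor activity", 49, 0.002, 0.266),
        ("Translation regulator activity", 38, 0.002, 0.266),
        ("Transferase activity transferring hexosyl groups", 75, 0.002, 0.266),
    ],
    "mixedmodel": [
        ("Regulation of axonogenesis", 10, "<0.001", "<0.001"),
        ("Regulation of neurogenesis", 14, "<0.001", 0.003),
        ("Central nervous system development", 122, "<0.001", 0.005),
        ("Ligase activity forming carbon nitrogen bonds", 68, "<0.001", 0.009),
        ("Ubiquitin protein ligase activity", 49, "<0.001", 0.013),
        ("Small conjugating protein ligase activity", 51, "<0.001", 0.014),
        ("Glycoprotein catabolic process", 12, "<0.001", 0.031),
        ("Axonogenesis", 43, "<0.001", 0.035),
        ("Cell matrix junction", 16, "<0.001", 0.035),
    ],
}

#: contributing genes (>= 1 SNP with association p < 0.05) of two reported sets
CARIES_CONTRIBUTING_GENES: dict[str, list[str]] = {
    "Regulation of axonogenesis": [
        "RTN4", "KLK8", "ROBO1", "MAPT", "ROBO2", "LRRC4C", "SLIT2",
    ],
    "Regulation of neurogenesis": [
        "RTN4", "KLK8", "ROBO1", "MAPT", "ROBO2", "LRRC4C", "SLIT2",
    ],
}


def caries_top_terms(method: str | None = None) -> pd.DataFrame:
    """Per-method top-9 GO terms (method, set, size, raw_p, fdr).

    The ``fdr`` column carries the FDR values as published, computed in the
    original analysis over all 1,331 tested sets; they are not recoverable
    from the top lists alone.

    Censored entries are replaced by :data:`CENSORED_P` so the frame is
    numeric; use the ranks, not the censored values themselves.
    """
    methods = [method] if method else list(_TOP_TERMS)
    rows = []
    for m in methods:
        if m not in _TOP_TERMS:
            raise KeyError(f"unknown method {m!r}")
        for name, size, p, fdr in _TOP_TERMS[m]:
            rows.append(
                (
                    m, name, size,
                    CENSORED_P if isinstance(p, str) else p,
                    CENSORED_P if isinstance(fdr, str) else fdr,
                )
            )
    return pd.DataFrame(rows, columns=["method", "set", "size", "raw_p", "fdr"])
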