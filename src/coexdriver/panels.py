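"""Curated NF-κB regulator panels.

The five NF-κB transcription-factor family members (``NKPF_FAMILY``) and the
31 pathway regulators ("seed genes", ``SEED_GENES``) recovered from the
published TNF-α / LPS secondary RNAi screens on THP-1 monocytes.  Together
they form the 36-gene panel the rheumatoid-arthritis analysis is anchored on.
"""

from __future__ import annotations

from .io import GenePanel, merge_regulator_panels

NKPF_FAMILY: tuple[str, ...] = ("NFKB1", "NFKB2", "REL", "RELA", "RELB")

SEED_GENES: tuple[str, ...] = (
    "CLCN2", "CRHR2", "FOSB", "GHRH", "GRIN2B", "KEL", "KPNA1", "NEFM",
    "PRKCG", "CX3CL1", "TLR4", "TNFRSF1A", "TRPC6", "UCHL3", "RIPK1",
    "CFLAR", "KDM4A", "CALCOCO2", "APC2", "ATG7", "SNW1", "BHMT2", "BMP10",
    "BFAR", "CINP", "PARVA", "HAPLN2", "ITCH", "DUSP15", "LIX1", "LCE1B",
)


def reconstructed_screen_lists() -> tuple[list[str], list[str], list[str]]:
    """Synthetic reconstruction of the two 20-hit screen lists.

    The source study reports only the merged panel plus its overlap
    structure: 20 TNF-α hits, 20 LPS hits, 8 genes shared between the
    screens, and RELA present in both screens and the family.  The split of
    the 31 seed genes between the screens was not published, so this helper
    partitions them deterministically in a way that reproduces those counts
    exactly; it is a stand-in, not the original screen output.
    """
    shared_seeds = list(SEED_GENES[:7])            # 7 seeds + RELA = 8 shared
    tnf_only = list(SEED_GENES[7:19])              # 12 unique TNF-α hits
    lps_only = list(SEED_GENES[19:31])             # 12 unique LPS hits
    tnf = tnf_only + shared_seeds + ["RELA"]       # 20 hits
    lps = lps_only + shared_seeds + ["RELA"]       # 20 hits
    return tnf, lps, list(NKPF_FAMILY)


def default_panel() -> GenePanel:
    """The 36-gene panel: 31 seed genes plus the 5-member NF-κB family."""
    tnf, lps, family = reconstructed_screen_lists()
    return merge_regulator_panels(tnf, lps, family, name="nfkb_regulators")
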