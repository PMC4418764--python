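"""miRNA identifier normalization shared across modules."""

from __future__ import annotations


#: Mature miRNAs withdrawn from miRBase (normalized keys). miR-768 was
#: retired in miRBase v12: its hairpin is a fragment of the snoRNA HBII-239,
#: so array probes for it do not report a bona fide miRNA. Retired ids stay
#: in per-grade differential tables but are not valid candidate miRNAs.
RETIRED_MIRNAS = frozenset({"mir-768-3p", "mir-768-5p"})


def normalize_mirna_id(mirna_id: str) -> str:
    """Canonical matching key for a miRNA identifier.

    Identifiers are matched case-insensitively after stripping an optional
    species prefix ("hsa-"), so that e.g. ``hsa-miR-200c``, ``miR-200c`` and
    ``mir-200c`` all collide. Proprietary probe ids (``miRplus-*``) pass
    through unchanged apart from case folding.
    """
    key = mirna_id.strip()
    if key.lower().startswith("hsa-"):
        key = key[4:]
    return key.lower()


def strip_species_prefix(mirna_id: str) -> str:
    """Display form: drop a leading ``hsa-`` but preserve the original case."""
    mirna_id = mirna_id.strip()
    if mirna_id.lower().startswith("hsa-"):
        return mirna_id[4:]
    return mirna_id
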