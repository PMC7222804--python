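"""Canonical mitochondrial locus names.

Annotation sources spell the same locus many ways (``tRNA-Trp``, ``trnW``,
``TRNW``; ``s-rRNA``, ``rrnS``, ``12S ribosomal RNA``).  Reports and
cross-species summaries align features by the canonical short names used
throughout comparative mtDNA work (TRNW, 12s rRNA, ND1, ...).
"""

from __future__ import annotations

_AA3 = {
    "Phe": "F", "Val": "V", "Leu": "L", "Ile": "I", "Met": "M",
    "Trp": "W", "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y",
    "Ser": "S", "Asp": "D", "Lys": "K", "Gly": "G", "Arg": "R",
    "His": "H", "Glu": "E", "Thr": "T", "Pro": "P", "Gln": "Q",
}

CANONICAL_NAMES: dict[str, str] = {
    # rRNAs
    "S-RRNA": "12s rRNA",
    "RRNS": "12s rRNA",
    "12S RRNA": "12s rRNA",
    "12S RIBOSOMAL RNA": "12s rRNA",
    "SMALL SUBUNIT RIBOSOMAL RNA": "12s rRNA",
    "L-RRNA": "16s rRNA",
    "RRNL": "16s rRNA",
    "16S RRNA": "16s rRNA",
    "16S RIBOSOMAL RNA": "16s rRNA",
    "LARGE SUBUNIT RIBOSOMAL RNA": "16s rRNA",
    # protein genes
    "COI": "COX1", "COII": "COX2", "COIII": "COX3",
    "CO1": "COX1", "CO2": "COX2", "CO3": "COX3",
    "COB": "CYTB", "CYB": "CYTB", "MT-CYB": "CYTB",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    # non-coding
    "D-LOOP": "D-LOOP", "CONTROL REGION": "D-LOOP",
    "OL": "rep_origin", "O_L": "rep_origin", "REP_ORIGIN": "rep_origin",
    "L-STRAND ORIGIN": "rep_origin",
    "AT REGION": "AT-REGION", "AT-RICH REGION": "AT-REGION",
}

# tRNA-Trp / trnW-style names
for _three, _one in _AA3.items():
    CANONICAL_NAMES[f"TRNA-{_three.upper()}"] = f"TRN{_one}"
    CANONICAL_NAMES[f"TRN{_one}"] = f"TRN{_one}"
# the two serine / leucine isoacceptors
CANONICAL_NAMES.update({
    "TRNL1": "TRNL1", "TRNL2": "TRNL2", "TRNS1": "TRNS1", "TRNS2": "TRNS2",
    "TRNA-LEU(UUR)": "TRNL1", "TRNA-LEU(CUN)": "TRNL2",
    "TRNA-SER(UCN)": "TRNS2", "TRNA-SER(AGY)": "TRNS1",
})
# MT-prefixed human-style symbols (MT-ND1, MT-CO1, MT-TW ...)
for _sym, _canon in list(CANONICAL_NAMES.items()):
    CANONICAL_NAMES.setdefault(f"MT-{_sym}", _canon)


def canonical_name(raw: str) -> str:
    """Map a raw locus label to its canonical short name.

    Unknown labels pass through unchanged (upper-cased only when they look
    like gene symbols already).
    """
    key = raw.strip().upper()
    if key in CANONICAL_NAMES:
        return CANONICAL_NAMES[key]
    return raw.strip()
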