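"""Canonical residue and secondary-structure orderings.

Two fixed orderings of the 20 standard amino acids are used throughout:

* ``PSSM_ORDER`` — the column order PSI-BLAST prints in its ASCII profile
  header (``A R N D C Q E G H I L K M F P S T W Y V``).  All PSSM-derived
  feature schemas use it.
* ``ALPHA_ORDER`` — plain alphabetical single-letter order, used for the
  n-gram and pseudo amino-acid composition schemas.

Features are consumed positionally by the classifier, so any fixed order
would do; these two are frozen so that feature tables are reproducible.
"""

PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"
ALPHA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AMINO_ACIDS = frozenset(ALPHA_ORDER)

#: secondary-structure states: helix, sheet, coil
SS_STATES = "HEC"

#: column order of the per-residue probability triple in a .ss2 file
SS2_PROB_ORDER = "CHE"
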