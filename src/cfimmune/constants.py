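"""Physical and assay constants used throughout the package.

Each constant is defined exactly once; downstream code imports from here
rather than re-deriving, so printed-method arithmetic is reproduced without
rounding drift.
"""

#: Mass of one haploid human genome, picograms.
HAPLOID_GENOME_PG: float = 3.3

#: Haploid genome equivalents per nanogram of DNA: 1000 pg / 3.3 pg,
#: rounded to the integer constant used by the quantification step.
GENOMES_PER_NG: int = 303

#: Default divisor applied to the raw neutrophil marker fraction.
NEUTROPHIL_DIVISOR: float = 0.69

#: Minimum percent identity to a converted reference for read retention.
DEFAULT_MIN_IDENTITY: float = 80.0

#: Reciprocal hemagglutination-inhibition titer scored antibody-positive.
HI_TITER_CUTOFF: int = 40

#: Advisory upper bound on amplicon length (bp), set by cfDNA fragment size.
AMPLICON_LENGTH_ADVISORY: int = 160
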