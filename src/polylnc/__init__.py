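"""polylnc: lncRNA origin and dynamics in hybrid and allopolyploid genomes.

A reusable pipeline covering lncRNA identification (length / positional
class / coding-potential filters), synteny-based ST/SA homology calls
between (sub)genomes, transposable-element overlap attribution with
family enrichment, mid-parent expression comparison for hybrids, and
DNA-methylation / small-RNA landscape profiling — plus a synthetic data
generator with planted ground truth for end-to-end validation.
"""

from .core import (
    CountMatrix,
    CytosineRecord,
    GenomicInterval,
    HomologyHit,
    PolylncError,
    TEFeature,
    TranscriptModel,
)

__version__ = "0.1.0"

__all__ = [
    "CountMatrix",
    "CytosineRecord",
    "GenomicInterval",
    "HomologyHit",
    "PolylncError",
    "TEFeature",
    "TranscriptModel",
    "__version__",
]
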