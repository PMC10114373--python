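"""Worked-example cell-type composition arithmetic.

Reference cell counts from a dissociated OSCC lymph-node metastasis
profiled by multiplexed scRNA-seq (one lesion, 4076 annotated cells) and
from the fibroblast/pericyte compartment of the full cohort (1595
fibroblasts).  The helper turns any count table into percentages of its
total, which is how the composition figures of such studies are reported.
"""

from __future__ import annotations

from .errors import ValidationError

#: Cell-type counts of a single metachronous lymph-node metastasis.
METASTASIS_CELL_TYPE_COUNTS = {
    "tumor": 1906,
    "fibroblast": 1186,
    "dendritic": 507,
    "macrophage": 375,
    "endothelial": 102,
}

#: Fibroblast-phenotype counts of the cohort's fibroblast compartment.
FIBROBLAST_PHENOTYPE_COUNTS = {
    "ecm": 1071,
    "immunomodulating": 311,
    "myofibroblast": 144,
    "frc": 41,
    "myoblast": 28,
}


def composition_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percentage of the total for each category, rounded to ``decimals``.

    The denominator is the sum of the given counts, i.e. the annotated
    cells of the compartment in question.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("counts must sum to a positive total")
    if any(v < 0 for v in counts.values()):
        raise ValidationError("counts must be non-negative")
    return {k: round(v / total * 100.0, decimals) for k, v in counts.items()}
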