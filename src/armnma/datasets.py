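"""Bundled example dataset: the smoking-cessation network.

24 randomized trials compare four smoking-cessation interventions —
no contact (reference), self-help, individual counselling and group
counselling — on successful cessation at 6-12 months.  Counts are
transcribed from Hasselblad (1998), the source used by many methodological
studies of mixed treatment comparisons (also distributed as
``dat.hasselblad1998`` in the R package metafor, against which this
transcription was checked).

Two trials — Cottraux et al. 1983 (the network's first 3-arm trial) and
Williams and Hall 1988 — are the only trials comparing no contact with
group counselling directly.  Removing them
(:data:`REMOVED_FOR_INDIRECT_NETWORK`) yields a reduced 22-trial network in
which group counselling is connected to the reference only through indirect
paths, a structure useful for stress-testing parameterizations.
"""

from __future__ import annotations

import io

import pandas as pd

from .data import NmaDataset

__all__ = [
    "TREATMENTS",
    "REFERENCE_TREATMENT",
    "REMOVED_FOR_INDIRECT_NETWORK",
    "load_smoking",
]

#: Treatment labels in index order (reference first).
TREATMENTS = (
    "no_contact",
    "self_help",
    "individual_counselling",
    "group_counselling",
)

REFERENCE_TREATMENT = TREATMENTS[0]

#: The only two trials directly comparing no contact with group counselling;
#: removing them leaves only indirect paths between those treatments.
REMOVED_FOR_INDIRECT_NETWORK = ("Cottraux 1983", "Williams and Hall 1988")

_SMOKING_CSV = """\
study,treatment,events,size
Reid 1974,no_contact,75,731
Reid 1974,individual_counselling,363,714
Cottraux 1983,no_contact,9,140
Cottraux 1983,individual_counselling,23,140
Cottraux 1983,group_counselling,10,138
Slama 1990,no_contact,2,106
Slama 1990,individual_counselling,9,205
Jamrozik 1984,no_contact,58,549
Jamrozik 1984,individual_counselling,237,1561
Rabkin 1984,no_contact,0,33
Rabkin 1984,individual_counselling,9,48
Decker and Evans 1989,self_help,20,49
Decker and Evans 1989,individual_counselling,16,43
Richmond 1986,no_contact,3,100
Richmond 1986,individual_counselling,31,98
Leung 1991,no_contact,1,31
Leung 1991,individual_counselling,26,95
Mothersill 1988,self_help,11,78
Mothersill 1988,individual_counselling,12,85
Mothersill 1988,group_counselling,29,170
Langford 1983,no_contact,6,39
Langford 1983,individual_counselling,17,77
Gritz 1992,no_contact,79,702
Gritz 1992,self_help,77,694
Campbell 1986,no_contact,18,671
Campbell 1986,self_help,21,535
Sanders 1989,no_contact,64,642
Sanders 1989,individual_counselling,107,761
Hilleman 1993,individual_counselling,12,76
Hilleman 1993,group_counselling,20,74
Gillams 1984,individual_counselling,9,55
Gillams 1984,group_counselling,3,26
Mogielnicki 1986,self_help,7,66
Mogielnicki 1986,group_counselling,32,127
Page 1986,no_contact,5,62
Page 1986,individual_counselling,8,90
Vetter and Ford 1990,no_contact,20,234
Vetter and Ford 1990,individual_counselling,34,237
Williams and Hall 1988,no_contact,0,20
Williams and Hall 1988,group_counselling,9,20
Pallonen 1994,no_contact,8,116
Pallonen 1994,self_help,19,149
Russell 1983,no_contact,95,1107
Russell 1983,individual_counselling,143,1031
Stewart and Rosser 1982,no_contact,15,187
Stewart and Rosser 1982,individual_counselling,36,504
Russell 1979,no_contact,78,584
Russell 1979,individual_counselling,73,675
Kendrick 1995,no_contact,69,1177
Kendrick 1995,individual_counselling,54,888
"""


def load_smoking(reduced: bool = False) -> NmaDataset:
    """Load the smoking-cessation network.

    Parameters
    ----------
    reduced
        If True, drop the two trials in :data:`REMOVED_FOR_INDIRECT_NETWORK`,
        leaving 22 trials in which group counselling is only indirectly
        connected to the no-contact reference.
    """
    frame = pd.read_csv(io.StringIO(_SMOKING_CSV), dtype={"study": str, "treatment": str})
    data = NmaDataset.from_frame(
        frame, REFERENCE_TREATMENT, treatment_order=TREATMENTS
    )
    if reduced:
        data = data.remove_studies(REMOVED_FOR_INDIRECT_NETWORK)
    return data
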