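"""Reported consensus partitions from the auditory EEG study.

These are the published four-cluster consensus partitions of the 12
three-symbol strings, retrieved from the right-prefrontal (RPF) and
central-prefrontal (CNT) electrode sets of the 19-participant study
whose design this package operationalizes.  They serve as observed
partitions for the Monte-Carlo significance analysis (their null
probabilities were reported as 0.0174 and 0.018 respectively) and in
the RPF case 9 of the 12 strings fall in the expected block of the
strong-beat partition under the best one-to-one cluster matching.
"""

from .partition import Partition

__all__ = ["RPF_CONSENSUS", "CNT_CONSENSUS"]

#: consensus partition retrieved from the right-prefrontal electrodes
RPF_CONSENSUS = Partition(
    [
        ["012", "002", "101"],
        ["021", "020", "121"],
        ["200", "210", "000"],
        ["001", "100", "120"],
    ]
)

#: consensus partition retrieved from the central-prefrontal electrodes
CNT_CONSENSUS = Partition(
    [
        ["012", "002", "001"],
        ["120", "020", "021"],
        ["200", "210", "101"],
        ["121", "100", "000"],
    ]
)
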