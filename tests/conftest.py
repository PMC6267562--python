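from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from spacerviz.records import CrisprLocus, Dataset, SpacerRecord

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_dataset(samples: dict[str, list[list[str]]]) -> Dataset:
    """Assemble a Dataset from {sample: [locus1_seqs, locus2_seqs, ...]}.

    Coordinates are synthesized consecutively; everything on the plus strand.
    """
    ds = Dataset()
    for sample_id, loci in samples.items():
        pos = 100
        for locus_num, seqs in enumerate(loci, start=1):
            locus = CrisprLocus(sample_id, locus_num, "+")
            for spacer_num, seq in enumerate(seqs, start=1):
                start = pos
                end = pos + len(seq) - 1
                locus.spacers.append(
                    SpacerRecord(sample_id, locus_num, spacer_num, start, end, "+", seq)
                )
                pos = end + 40
            ds.add_locus(locus)
    ds.validate()
    return ds


@pytest.fixture
def two_sample_ds() -> Dataset:
    return build_dataset(
        {
            "SA": [["ACGTACGTACGTACGTACGTACGTACGTAC", "TTTTCCCCGGGGAAAATTTTCCCCGGGGAA"]],
            "SB": [["ACGTACGTACGTACGTACGTACGTACGTAC", "GATCGATCGATCGATCGATCGATCGATCGA"]],
        }
    )
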