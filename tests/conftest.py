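import pytest

import pcbdechlor as pcb

#: every congener name printed in the source screening tables and
#: narrative (losses, gains, intermediates, spiked congeners)
PRINTED_CONGENER_NAMES = sorted(
    {
        "245-245-CB", "234-245-CB", "2345-245-CB", "2345-236-CB",
        "2345-25-CB", "235-25-CB", "25-25-CB", "245-24-CB", "235-245-CB",
        "24-25-CB", "2345-234-CB", "2346-245-CB", "2345-26-CB",
        "245-25-CB", "234-236-CB", "235-34-CB", "236-245-CB", "236-24-CB",
        "2356-245-CB", "236-25-CB", "24-24-CB", "2356-24-CB", "24-26-CB",
        "24-2-CB", "236-34-CB", "2356-234-CB", "25-26-CB", "234-25-CB",
        "2345-CB", "2356-CB", "23456-CB",
    }
)

#: published loss/gain lists for the CW-4 microcosm screening row
CW4_LOSSES = [
    "245-245-CB", "234-245-CB", "2345-245-CB",
    "2345-236-CB", "2345-25-CB", "2345-234-CB",
]
CW4_GAINS = ["25-25-CB", "235-25-CB", "24-25-CB", "2345-26-CB"]


@pytest.fixture(scope="session")
def control_homologs():
    """Homolog-level profile of the undechlorinated control mixture."""
    return pcb.homolog_profile(
        pcb.AROCLOR1260_CONTROL_HOMOLOGS, total_um=81.0, label="control"
    )


@pytest.fixture(scope="session")
def dechlorinated_homologs():
    """Homolog-level profile after 3 months of extensive dechlorination."""
    return pcb.homolog_profile(
        pcb.DECHLORINATED_CG5_HOMOLOGS, total_um=81.0, label="dechlorinated"
    )


@pytest.fixture(scope="session")
def builtin_candidates():
    return [pcb.builtin_process(n) for n in ("H", "N", "T", "CG1")]
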