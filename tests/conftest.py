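import pytest

from helpers import build_pedigree
from lynchtriage.reference import marginal_lab_cohort


@pytest.fixture
def trio():
    """Father, mother, affected child proband with one colorectal tumour."""
    return build_pedigree(
        rows=[("C1", "F1", "M1", "female"), ("F1", None, None, "male"),
              ("M1", None, None, "female")],
        tumors=[("C1", "colorectal", 45)],
        proband="C1",
    )


@pytest.fixture
def three_generation():
    """Proband with sibling, parents, maternal aunt (plus her husband and
    son) and grandparents on both sides."""
    return build_pedigree(
        rows=[
            ("PB", "FA", "MO", "female"),
            ("SB", "FA", "MO", "male"),
            ("FA", "GFP", "GMP", "male"),
            ("MO", "GFM", "GMM", "female"),
            ("GFP", None, None, "male"),
            ("GMP", None, None, "female"),
            ("GFM", None, None, "male"),
            ("GMM", None, None, "female"),
            ("AUNT", "GFM", "GMM", "female"),
            ("AUNT_HUSB", None, None, "male"),
            ("COUSIN", "AUNT_HUSB", "AUNT", "male"),
        ],
        tumors=[("PB", "colorectal", 45)],
        proband="PB",
    )


@pytest.fixture
def marginal_cohort():
    """Cohort with the historical referral series' margins (372 probands,
    368 tested, 92 deficient, 114 screened, 48 mutation carriers)."""
    return marginal_lab_cohort()
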