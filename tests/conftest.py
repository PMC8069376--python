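"""Shared fixtures: small synthetic marker families and communities."""

import numpy as np
import pytest

from capturesim.community_sim import MarkerFamilySpec, generate_marker_family
from capturesim.marker_db import CpnType, Domain, MarkerDB, MarkerRecord

from _helpers import random_dna


@pytest.fixture(scope="session")
def small_family() -> MarkerDB:
    """Six related records (UT 549-567 nt with 400 nt flanks)."""
    return generate_marker_family(
        MarkerFamilySpec(n_taxa=6, seed=42, target_identity_range=(0.72, 0.85))
    )


@pytest.fixture(scope="session")
def ut_only_family() -> MarkerDB:
    """Eight UT-only records (no flanks), e.g. cloned amplicon panel."""
    return generate_marker_family(
        MarkerFamilySpec(n_taxa=8, seed=7, flank_length=0,
                         target_identity_range=(0.72, 0.85))
    )


@pytest.fixture()
def single_record() -> MarkerRecord:
    rng = np.random.default_rng(123)
    seq = random_dna(rng, 1355)
    return MarkerRecord(
        id="rec0", taxon="Test sp.", domain=Domain.BACTERIA, cpn_type=CpnType.I,
        seq=seq, ut_interval=(400, 955),
    )
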