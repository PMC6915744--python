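import numpy as np
import pytest

from methsig.conformational import PentamerShapeTable
from methsig.preprocess import DMSRecord
from methsig.regulatory import acceptor_model, donor_model, pfm_to_pwm
from methsig.seqcontext import SequenceWindow
from methsig.simulate import fixture_pfm


def make_window(
    seq: str,
    center: int | None = None,
    chrom: str = "chrT",
    origin: int = 0,
    delta_beta: float = 0.0,
    site_id: str | None = None,
) -> SequenceWindow:
    """Wrap a raw sequence into a SequenceWindow centered at ``center``."""
    if center is None:
        center = len(seq) // 2
    site = DMSRecord(chrom, origin + center, origin + center + 1,
                     delta_beta=delta_beta, site_id=site_id)
    return SequenceWindow(
        site=site,
        offset=max(center, len(seq) - center),
        sequence=seq.upper(),
        window_start=origin,
        window_end=origin + len(seq),
    )


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@pytest.fixture(scope="session")
def shape_table() -> PentamerShapeTable:
    return PentamerShapeTable.synthetic(seed=11)


@pytest.fixture(scope="session")
def donor():
    return donor_model()


@pytest.fixture(scope="session")
def acceptor():
    return acceptor_model()


@pytest.fixture(scope="session")
def fixture_pwm():
    return pfm_to_pwm(fixture_pfm())
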