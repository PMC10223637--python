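import numpy as np
import pytest

from lactopk.io_cli import load_fixture
from lactopk.milk_transfer import MilkTransferParams, derive_milk_transfer
from lactopk.physchem import DrugPhysChem, GroupKind, IonizationGroup
from lactopk.pk_engine import MaternalPKParams, build_model


def make_transfer(clsec=100.0, clre=200.0, fu_milk_total=1.0, pmilk=0.0, fu_skim=1.0):
    """Hand-built transfer record (clearances in mL/h) for engine tests."""
    mp = 0.0 if clsec == 0 or clre == 0 else clsec / (fu_milk_total * clre)
    return MilkTransferParams(
        clsec=clsec, clre=clre, pmilk=pmilk, fu_skim=fu_skim,
        fu_milk_total=fu_milk_total, mp_ss=mp,
    )


@pytest.fixture(scope="session")
def neutral_probe():
    return DrugPhysChem(name="probe", mw=200.0, logp=0.0, psa=50.0, fu_plasma=1.0)


@pytest.fixture(scope="session")
def weak_acid():
    return DrugPhysChem(
        name="acid-probe", mw=150.0, logp=2.75,
        groups=(IonizationGroup(GroupKind.acid, 4.80),),
        hbd=1, hba=2, psa=37.3, fu_plasma=0.14,
    )


@pytest.fixture(scope="session")
def caffeine_config():
    return load_fixture("caffeine")


@pytest.fixture(scope="session")
def caffeine_model(caffeine_config):
    return build_model(
        caffeine_config.physchem,
        caffeine_config.maternal_pk,
        derive_milk_transfer(caffeine_config.physchem),
    )


@pytest.fixture
def iv_model(neutral_probe):
    """1-compartment IV-only model with milk transfer switched off."""
    pk = MaternalPKParams(cl=5.0, vc=50.0)
    return build_model(neutral_probe, pk, make_transfer(clsec=0.0, clre=0.0))


@pytest.fixture
def coupled_iv_model(neutral_probe):
    """1-compartment IV model with active milk exchange."""
    pk = MaternalPKParams(cl=5.0, vc=50.0)
    return build_model(neutral_probe, pk, make_transfer(clsec=400.0, clre=300.0,
                                                        fu_milk_total=0.8))
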