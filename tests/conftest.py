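import pytest

from ces1pbpk import load_drug, load_physiology

PARENT_DRUGS = ["enalapril", "benazepril", "cilazapril", "perindopril",
                "temocapril", "oseltamivir", "flumazenil", "pethidine",
                "remimazolam"]
METABOLITES = ["enalaprilat", "benazeprilat", "cilazaprilat", "perindoprilat",
               "temocaprilat", "oseltamivir_carboxylate"]


@pytest.fixture(scope="session")
def phys():
    return load_physiology()


@pytest.fixture(scope="session")
def healthy(phys):
    return phys["healthy"]


@pytest.fixture(scope="session")
def drugs():
    return {name: load_drug(name) for name in PARENT_DRUGS}
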