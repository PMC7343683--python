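"""Shared noise-free simulation fixtures.

Ground-truth parameter sets used across the suite:

* reference region: one-tissue kinetics with K1 = 0.1 mL/cm^3/min and
  efflux k2' = 0.1 min^-1;
* SRTM target: R1 = 1.2, k2 = 0.15 min^-1, BP_ND = 1.5 (DVR = 2.5);
* 2TCM target: K1 = 0.1, k2 = 0.12, k3 = 0.05, k4 = 0.03,
  so V_T = (K1/k2)(1 + k3/k4) = 2.2222...

Receptor-ligand (reference) scans use the 63-min schedule; the slowly
equilibrating 2TCM target uses the 120-min schedule so that the graphical
methods reach their asymptote.
"""

import numpy as np
import pytest

import petkin as pk

SRTM_TRUTH = {"r1": 1.2, "k2": 0.15, "bp_nd": 1.5}
TCM_TRUTH = {"K1": 0.1, "k2": 0.12, "k3": 0.05, "k4": 0.03}
TCM_VT = (TCM_TRUTH["K1"] / TCM_TRUTH["k2"]) * (1 + TCM_TRUTH["k3"] / TCM_TRUTH["k4"])
REF_TRUTH = {"K1": 0.1, "k2": 0.1}
#: true reference efflux constant implied by the SRTM truth (k2 / R1)
SRTM_K2PRIME = SRTM_TRUTH["k2"] / SRTM_TRUTH["r1"]


@pytest.fixture(scope="session")
def blood63():
    return pk.make_input()


@pytest.fixture(scope="session")
def blood120():
    return pk.make_input(t_end=120.0)


@pytest.fixture(scope="session")
def frames120():
    return pk.default_frames(120.0)


@pytest.fixture(scope="session")
def ref_tac(blood63):
    tac, _ = pk.simulate_tac("1tc", REF_TRUTH, blood=blood63, region_name="ref")
    return tac


@pytest.fixture(scope="session")
def srtm_target(ref_tac):
    tac, _ = pk.simulate_tac("srtm", SRTM_TRUTH, ref=ref_tac,
                             region_name="target")
    return tac


@pytest.fixture(scope="session")
def tcm_target(blood120, frames120):
    tac, _ = pk.simulate_tac("2tcm", TCM_TRUTH, blood=blood120,
                             frames=frames120, vB=0.05, region_name="target")
    return tac
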