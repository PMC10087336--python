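import numpy as np
import pytest

from tpcmeta.data_model import AssayRecord, EffectRecord
from tpcmeta.meta_model import PosteriorDraws


def make_effect(i=0, y=0.1, se=0.05, dt=0.0, study="s0", species="sp0",
                tpc="t0", sign="equal", var="de_novo", gens=10.0,
                n_temps=1, mode="discrete"):
    return EffectRecord(
        effect_id=f"e{i}", study_id=study, species_id=species, tpc_id=tpc,
        rel_fitness=y, rel_fitness_se=se, rel_assay_temp=dt, sign=sign,
        variation_source=var, generations=gens,
        n_assay_temps_in_tpc=n_temps, mode_used=mode)


def make_assay(tpc="t0", study="s0", species="sp0", mode="discrete",
               assay_temp=25.0, selection_temp=25.0, control_temp=25.0,
               f_sel=1.2, f_anc=1.0, disp_sel=0.1, disp_anc=0.1,
               disp_type="se", n_replicates=None, generation_time=None,
               generations=50.0, var="standing"):
    return AssayRecord(
        study_id=study, species_id=species, tpc_id=tpc,
        reproduction_mode=mode, variation_source=var,
        comparison="control", sexual=True, generations=generations,
        generation_time=generation_time, selection_temp=selection_temp,
        control_temp=control_temp, assay_temp=assay_temp,
        f_sel_mean=f_sel, f_anc_mean=f_anc, disp_sel=disp_sel,
        disp_anc=disp_anc, disp_type=disp_type, n_replicates=n_replicates)


def make_draws(sigma2, beta=None, level_names=None, u=None, colnames=None):
    """Hand-built PosteriorDraws for machinery tests (no sampling)."""
    sigma2 = np.atleast_2d(np.asarray(sigma2, float))
    d = sigma2.shape[0]
    level_names = tuple(level_names or
                        [f"lv{i}" for i in range(sigma2.shape[1])])
    beta = np.zeros((d, 1)) if beta is None else np.asarray(beta, float)
    colnames = tuple(colnames or [f"b{i}" for i in range(beta.shape[1])])
    u = u or {lvl: np.zeros((d, 1)) for lvl in level_names}
    return PosteriorDraws(beta=beta, sigma2=sigma2, u=u, colnames=colnames,
                          level_names=level_names, chains=1,
                          iterations=d + 1, warmup=1)


@pytest.fixture
def toy_effects():
    ys = [0.1, 0.3, -0.2, 0.5, 0.0]
    ss = [0.05, 0.1, 0.2, 0.1, 0.05]
    return [make_effect(i, y=y, se=s, tpc=f"t{i}")
            for i, (y, s) in enumerate(zip(ys, ss))]
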