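import numpy as np
import pytest

import tkburden as tk


@pytest.fixture
def study_times():
    return np.array(tk.STUDY_SAMPLING_TIMES_H)


def make_oral_series(k_a, k_e, v_over_f, dose=0.5, times=tk.STUDY_SAMPLING_TIMES_H,
                     noise_cv=0.0, rng=None, subject_id="s1", sex="male",
                     label="thiazol"):
    """Series following the closed-form oral curve, optional proportional noise."""
    params = tk.TKParameters(k_a=k_a, k_e=k_e, v_over_f=v_over_f, route="oral")
    d = tk.DoseSpec(dose, "oral")
    t = np.asarray(times, dtype=float)
    c = tk.oral_concentration(params, d, t)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        c = c * rng.lognormal(-sigma**2 / 2, sigma, size=t.size)
    return tk.ConcentrationSeries(subject_id, sex, label, d, tuple(t), tuple(float(x) for x in c))


def make_iv_series(k_e, v, dose=0.5, times=tk.STUDY_SAMPLING_TIMES_H,
                   noise_cv=0.0, rng=None, subject_id="s1", sex="male",
                   label="thiazol"):
    params = tk.TKParameters(k_e=k_e, v_over_f=v, route="iv")
    d = tk.DoseSpec(dose, "iv")
    t = np.asarray(times, dtype=float)
    c = tk.iv_concentration(params, d, t)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        c = c * rng.lognormal(-sigma**2 / 2, sigma, size=t.size)
    return tk.ConcentrationSeries(subject_id, sex, label, d, tuple(t), tuple(float(x) for x in c))
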