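"""Hand-computed oracle for the 3-age, 1-disease toy cohort comparison.

Built independently of the package: closed-form constant-rate solutions of
the illness-death system evaluated with ``math.exp`` only, and explicit
spreadsheet-style life-table arithmetic.  The toy configuration:

* one sex, ages 50-52, population 1000 per single-year age
* one chronic disease: incidence 0.01, case fatality 0.10, remission 0,
  disability weight 0.2, zero starting prevalence
* all-cause mortality 0.02, total morbidity rate 0.05 at every age
* healthcare cost 1000 per prevalent person-year
* PIF 0.5 on all ages, one-year horizon, no discounting
"""

import math

I, F, R, M = 0.01, 0.10, 0.0, 0.02
DW, W_TOTAL, COST, POP = 0.2, 0.05, 1000.0, 1000.0
PIF = 0.5
AGES = (50, 51, 52)


def _closed_form_p(i, f, m, t):
    """Prevalence among the living after t years from p(0) = 0, r = 0.

    S(t) = exp(-(i+m) t); C(t) = i/(f-i) (exp(-(i+m) t) - exp(-(f+m) t)).
    """
    s = math.exp(-(i + m) * t)
    c = i / (f - i) * (math.exp(-(i + m) * t) - math.exp(-(f + m) * t))
    return c / (s + c)


def expected_outputs():
    """Returns dict with halys_gained, cost_offset, deaths_averted, cases_prevented."""
    i_scn = I * (1.0 - PIF)

    p_bau = [_closed_form_p(I, F, M, t) for t in range(3)]
    p_scn = [_closed_form_p(i_scn, F, M, t) for t in range(3)]
    md_bau = [p * F for p in p_bau]
    md_scn = [p * F for p in p_scn]

    m_bau = [M] * 3
    m_scn = [M - (md_bau[k] - md_scn[k]) for k in range(3)]
    w_bau = [W_TOTAL] * 3
    w_scn = [W_TOTAL - (p_bau[k] - p_scn[k]) * DW for k in range(3)]

    halys = deaths = cases = cost = 0.0
    for k in range(3):  # one cohort per start age, one-year horizon
        l1_b = math.exp(-m_bau[k])
        l1_s = math.exp(-m_scn[k])
        L_b = 0.5 * (1.0 + l1_b)
        L_s = 0.5 * (1.0 + l1_s)
        halys += POP * (L_s * (1.0 - w_scn[k]) - L_b * (1.0 - w_bau[k]))
        deaths += POP * (L_b * md_bau[k] - L_s * md_scn[k])
        cases += POP * (L_b * (1.0 - p_bau[k]) * I - L_s * (1.0 - p_scn[k]) * i_scn)
        cost += POP * (L_b * p_bau[k] - L_s * p_scn[k]) * COST
    return {
        "halys_gained": halys,
        "deaths_averted": deaths,
        "cases_prevented": cases,
        "cost_offset": cost,
    }
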