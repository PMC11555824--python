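"""Hand-written spreadsheet-style oracle for a 2-stratum toy population.

Everything here is computed with explicit scalar arithmetic from the
documented model rules, never by calling the package, so it serves as an
independent check of the vectorized engines. The toy population,
modifiers and fiscal constants mirror the ``toy_*`` fixtures in
conftest.py.

Model rules applied by hand:
* employment marginal effect additive on each employment probability,
  income effect relative, welfare rates scaled by hazard ratios;
* retired persons leave the employment-eligible pool first; sick pay is
  2/3 of salary and (base case) applies to full-time workers only;
* direct tax = wedge x income; indirect tax = VAT x (disposable income
  + pension transfers);
* medical expenditure per capita split so non-OAO categories carry
  (1-AF) x MEPC and OAO categories additionally AF x MEPC / p_OAO,
  with the category profile always anchored on the control prevalence;
* Rockhill PAF with the case distribution pd_k = X_k RR_k / sum X RR,
  and half a person-year removed from the OAO group's labor/transfer
  flows per OAO-attributable death.
"""

# ---- toy parameters (keep in sync with conftest toy fixtures) -----------

WEDGE = 0.3
VAT = 0.1
PENSION = 10.0
SPF = 2.0 / 3.0

BETA_EMP = -0.05
BETA_INC = -0.1
HR_SL = 1.5
HR_RET = 1.25
RR = {"under": 1.0, "normal": 1.0, "over": 1.2, "obese": 1.5}
AF = 0.1

# (count, props[u,n,o,b], emp_ft, emp_pt, y_ft, y_pt, sick, ret, mepc, mort)
STRATUM_A = dict(
    count=100.0,
    props={"under": 0.1, "normal": 0.7, "over": 0.15, "obese": 0.05},
    emp_ft=0.6, emp_pt=0.1, y_ft=100.0, y_pt=40.0,
    sick=0.05, ret=0.0, mepc=10.0, mort=0.01,
)
STRATUM_B = dict(
    count=50.0,
    props={"under": 0.1, "normal": 0.6, "over": 0.2, "obese": 0.1},
    emp_ft=0.4, emp_pt=0.2, y_ft=80.0, y_pt=30.0,
    sick=0.04, ret=0.2, mepc=20.0, mort=0.02,
)

OAO = ("over", "obese")
NON_OAO = ("under", "normal")


def _cell_income(n, p_ft, p_pt, p_sl, p_ret, y_ft, y_pt):
    eligible = 1.0 - p_ret
    ft = p_ft * eligible * ((1.0 - p_sl) + p_sl * SPF) * y_ft
    pt = p_pt * eligible * y_pt
    return n * (ft + pt)


def _stratum_ledger(s, props, ref_props, oao_effects):
    """Flows for one stratum; ``props`` are the cohort's (possibly
    reassigned) proportions, ``ref_props`` the control prevalence that
    anchors the medical-cost profile."""
    count = s["count"]

    # healthcare profile anchored on the control prevalence
    p_oao_ref = ref_props["over"] + ref_props["obese"]
    base_cost = (1.0 - AF) * s["mepc"]
    oao_cost = base_cost + AF * s["mepc"] / p_oao_ref
    hc = count * (
        (props["under"] + props["normal"]) * base_cost
        + (props["over"] + props["obese"]) * oao_cost
    )

    # Rockhill PAF from the cohort's own prevalence
    sum_xr = sum(props[k] * RR[k] for k in props)
    paf = sum(
        (props[k] * RR[k] / sum_xr) * (RR[k] - 1.0) / RR[k] for k in props
    )
    deaths = paf * count * s["mort"]
    py_loss = 0.5 * deaths
    n_oao = count * (props["over"] + props["obese"])

    dt = it = tr = 0.0
    for k in props:
        n_k = count * props[k]
        if n_k <= 0.0:
            continue
        if k in OAO and oao_effects:
            n_k *= 1.0 - py_loss / n_oao
            p_ft = max(0.0, s["emp_ft"] + BETA_EMP)
            p_pt = max(0.0, s["emp_pt"] + BETA_EMP)
            p_sl = min(1.0, s["sick"] * HR_SL)
            p_ret = min(1.0, s["ret"] * HR_RET)
            y_ft = s["y_ft"] * (1.0 + BETA_INC)
            y_pt = s["y_pt"] * (1.0 + BETA_INC)
        else:
            p_ft, p_pt, p_sl, p_ret = s["emp_ft"], s["emp_pt"], s["sick"], s["ret"]
            y_ft, y_pt = s["y_ft"], s["y_pt"]
        income = _cell_income(n_k, p_ft, p_pt, p_sl, p_ret, y_ft, y_pt)
        pension = n_k * p_ret * PENSION
        dt += WEDGE * income
        it += VAT * ((1.0 - WEDGE) * income + pension)
        tr += pension
    return dt, it, tr, hc


def annual_ledger():
    """Control flows, intervention flows and the burden decomposition.

    Returns ((dt_c, it_c, tr_c, hc_c), (dt_i, it_i, tr_i, hc_i),
    (dt_loss, it_loss, tr_excess, hc_excess, total)).
    """
    control = [0.0, 0.0, 0.0, 0.0]
    interv = [0.0, 0.0, 0.0, 0.0]
    for s in (STRATUM_A, STRATUM_B):
        ref = s["props"]
        reassigned = {
            "under": ref["under"],
            "normal": ref["normal"] + ref["over"] + ref["obese"],
            "over": 0.0,
            "obese": 0.0,
        }
        for acc, props in ((control, ref), (interv, reassigned)):
            flows = _stratum_ledger(s, props, ref, oao_effects=True)
            for i in range(4):
                acc[i] += flows[i]
    dt_loss = interv[0] - control[0]
    it_loss = interv[1] - control[1]
    tr_x = control[2] - interv[2]
    hc_x = control[3] - interv[3]
    total = dt_loss + it_loss + tr_x + hc_x
    return tuple(control), tuple(interv), (dt_loss, it_loss, tr_x, hc_x, total)


# ---- lifetime toy -------------------------------------------------------
# One female stratum (ages 60-65), life table terminal age 65, start 63.
# Discount 5%/yr, no wage growth, pension 10/yr from retirement,
# statutory retirement at 65, early-retirement hazard from the stratum
# rate (0.2/yr, x1.25 for the OAO arm).

LT_DISCOUNT = 0.05
LT_QX = {63: 0.1, 64: 0.2, 65: 1.0}
LT_STRATUM = dict(
    props={"under": 0.1, "normal": 0.6, "over": 0.2, "obese": 0.1},
    emp_ft=0.4, emp_pt=0.2, y_ft=80.0, y_pt=30.0,
    sick=0.04, ret=0.2, mepc=20.0,
)


def lifetime_ledger():
    """Hand-discounted per-person ledger for start age 63.

    Returns (tax_loss, transfer_excess, total).
    """
    s = LT_STRATUM
    p_oao = s["props"]["over"] + s["props"]["obese"]  # 0.3
    rr_bar = (s["props"]["over"] * RR["over"] + s["props"]["obese"] * RR["obese"]) / p_oao

    # arm-specific rates
    ref_rates = dict(p_ft=s["emp_ft"], p_pt=s["emp_pt"], p_sl=s["sick"],
                     y_ft=s["y_ft"], y_pt=s["y_pt"])
    oao_rates = dict(
        p_ft=s["emp_ft"] + BETA_EMP, p_pt=s["emp_pt"] + BETA_EMP,
        p_sl=s["sick"] * HR_SL,
        y_ft=s["y_ft"] * (1.0 + BETA_INC), y_pt=s["y_pt"] * (1.0 + BETA_INC),
    )
    base_cost = (1.0 - AF) * s["mepc"]
    mepc_arm = {"ref": base_cost, "oao": base_cost + AF * s["mepc"] / p_oao}
    h_arm = {"ref": s["ret"], "oao": min(1.0, s["ret"] * HR_RET)}

    results = {}
    for arm, rates in (("ref", ref_rates), ("oao", oao_rates)):
        surv, retired = 1.0, 0.0
        pv_tax = pv_spend = 0.0
        for t, age in enumerate((63, 64, 65)):
            if age >= 65:
                retired = 1.0
            df = (1.0 + LT_DISCOUNT) ** (-t)
            income = _cell_income(
                1.0, rates["p_ft"], rates["p_pt"], rates["p_sl"], retired,
                rates["y_ft"], rates["y_pt"],
            )
            pension = retired * PENSION
            dt = WEDGE * income
            it = VAT * ((1.0 - WEDGE) * income + pension)
            pv_tax += surv * df * (dt + it)
            pv_spend += surv * df * (pension + mepc_arm[arm])
            qx_ref = LT_QX[age] / (1.0 - p_oao + p_oao * rr_bar)
            qx = min(1.0, rr_bar * qx_ref) if arm == "oao" else qx_ref
            surv *= 1.0 - qx
            if 50 <= age < 65:
                retired += (1.0 - retired) * h_arm[arm]
        results[arm] = (pv_tax, pv_spend)

    tax_loss = results["ref"][0] - results["oao"][0]
    transfer_excess = results["oao"][1] - results["ref"][1]
    return tax_loss, transfer_excess, tax_loss + transfer_excess
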