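#!/usr/bin/env python
"""Regenerate the packaged preset JSON files from the frozen tuned values.

The presets were tuned once against their biological anchors (bistability
and reversibility windows, the 8-day / 3-5-day TNC induction delays, the
5-ug activation threshold) and are versioned with the package; this script
only re-serialises them and re-checks the anchors.  Run from the repo root:

    python scripts/tune_presets.py [--check]
"""

import argparse
import json
from pathlib import Path

OUTDIR = Path(__file__).resolve().parents[1] / "src" / "pflswitch" / "presets"

DOX_REFERENCE = dict(
    basal_Tw=1e-3, basal_P=1e-3, basal_T=1e-3,
    vmax_dox=10.0, km_dox=1.0, n_dox=1.0,
    v_feedback=35.0, km_feedback=5.0, n_feedback=1.0,
    vmax_TwP=5.0, km_TwP=15.0, n_TwP=2.0,
    vmax_PT=5.0, km_PT=8.0, n_PT=2.0,
    deg_Tw=1.0, deg_P=0.5, deg_T=0.5,
)

#: rate-dimension fields; a global time rescale multiplies exactly these,
#: preserving every equilibrium and bifurcation property
RATE_FIELDS = ("basal_Tw", "basal_P", "basal_T", "vmax_dox", "v_feedback",
               "vmax_TwP", "vmax_PT", "deg_Tw", "deg_P", "deg_T")

#: TNC 2-fold induction delay (days) of the reference model under a dox
#: step of level 1.0 — measured once, used to rescale MRC5/IMR90 kinetics
T_DELAY_REF = 1.8741275156210522

DERMAL_INJECTION = dict(
    basal_Tw=2.0, basal_P=0.3, basal_T=0.3,
    vmax_dox=0.0, km_dox=1.0, n_dox=1.0,
    v_feedback=30.0, km_feedback=5.0, n_feedback=4.0,
    vmax_TwP=6.0, km_TwP=10.0, n_TwP=4.0,
    vmax_PT=8.0, km_PT=4.0, n_PT=4.0,
    deg_Tw=1.0, deg_P=1.0, deg_T=1.0,
)


def rescaled(base: dict, alpha: float) -> dict:
    return {k: (v * alpha if k in RATE_FIELDS else v) for k, v in base.items()}


def build() -> dict:
    return {
        "dox_reference": {
            "schema": 1,
            "mode": "dox",
            "description": "Reference dox-induction model: bistable and reversible "
                           "at the default feedback strength, irreversible at "
                           "v_feedback >= ~42.",
            "dox_level": 1.0,
            "bistable_stimulus": 0.5,
            "parameters": DOX_REFERENCE,
        },
        "mrc5": {
            "schema": 1,
            "mode": "dox",
            "description": "MRC5-like fibroblast preset: reference model "
                           "time-rescaled so the TNC 2-fold induction delay at "
                           "dox level 1.0 is 8 days.",
            "dox_level": 1.0,
            "bistable_stimulus": 0.5,
            "parameters": rescaled(DOX_REFERENCE, T_DELAY_REF / 8.0),
        },
        "imr90": {
            "schema": 1,
            "mode": "dox",
            "description": "IMR90-like fibroblast preset: reference model "
                           "time-rescaled so the TNC 2-fold induction delay at "
                           "dox level 1.0 is 4 days.",
            "dox_level": 1.0,
            "bistable_stimulus": 0.5,
            "parameters": rescaled(DOX_REFERENCE, T_DELAY_REF / 4.0),
        },
        "dermal_injection": {
            "schema": 1,
            "mode": "tnc_injection",
            "description": "Dermal-fibroblast exogenous-TNC injection model at "
                           "the irreversible anchor (km_feedback, v_feedback) = "
                           "(5, 30); reversible at (10, 15). 1 ug of exogenous "
                           "TNC maps to 1 a.u. of stimulus.",
            "dose_scale": 1.0,
            "parameters": DERMAL_INJECTION,
        },
    }


def check() -> None:
    """Re-verify the anchors the presets were tuned against."""
    import numpy as np

    from pflswitch import equilibria, model, presets, protocols, switch, synth

    p = presets.load_params("dox_reference")
    grid = np.linspace(0.0, 2.0, 81)
    h = switch.hysteresis(p, grid, method="continuation")
    assert h.reversible and h.bistable, "reference model must show reversible hysteresis"
    h80 = switch.hysteresis(p.replace(v_feedback=80.0), grid, method="continuation")
    assert h80.delta_tnc > switch.EPS_REV, "v_feedback=80 must be irreversible"

    for name, target in (("mrc5", 8.0), ("imr90", 4.0)):
        pp = presets.load_params(name)
        init = equilibria.find_fixed_points(pp, 0.0, "dox")[0].state
        traj = model.integrate(pp, protocols.dox_step(1.0, 0.0, 20.0), init,
                               np.linspace(0.0, 20.0, 2001))
        delay = protocols.induction_delay(traj, "T", 2.0)
        assert abs(delay - target) < 0.05, f"{name}: delay {delay} != {target}"

    ds = synth.generate_dose_response(noise_sd=0.0, n_reps=1)
    active = (ds.tw_fold[0] > 2.0) & (ds.t_fold[0] > 2.0)
    assert list(ds.doses[active]) == [5.0], "activation threshold must be 5 ug"
    print("all preset anchors verified")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--check", action="store_true",
                    help="re-verify anchors after writing")
    args = ap.parse_args()
    for name, data in build().items():
        path = OUTDIR / f"{name}.json"
        path.write_text(json.dumps(data, indent=1) + "\n")
        print("wrote", path)
    if args.check:
        check()


if __name__ == "__main__":
    main()
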