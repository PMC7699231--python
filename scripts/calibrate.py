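#!/usr/bin/env python
"""Show how the packaged default exposure factors are calibrated.

Two screening outputs anchor the otherwise under-determined defaults:

* ingestion: MR = 10 mg/cm2/h must give 5.0e-1 mg/kg/d, solved for the
  mouthing duration D_mouthing (linear, closed form);
* dermal: DEHP at the 0.01% w/w inclusion-threshold content must give
  8.6e-6 mg/kg/d, solved for the solid-phase diffusion coefficient D
  (FA and t_lag do not depend on D, so also closed form).

Run after editing any base factor to regenerate the calibrated preset.
"""

from plastexpo.chemistry import get_chemical
from plastexpo.dermal import (
    FACTOR_PRESETS,
    content_to_cart,
    default_factors,
    dermal_daily_dose,
    dermal_intermediates,
)
from plastexpo.ingestion import ingestion_daily_dose


def main() -> None:
    for preset in sorted(FACTOR_PRESETS):
        f = default_factors(preset)
        inter = dermal_intermediates(get_chemical("DEHP"), f)
        anchor = dermal_daily_dose(content_to_cart(1e-4, f.rho_article), f, inter)
        print(f"{preset}:")
        print(f"  calibrated D_mouthing = {f.d_mouthing:.6g} min/h")
        print(f"  calibrated D          = {f.d:.6g} m2/h")
        print(f"  check ingestion @ MR=10: {ingestion_daily_dose(10.0, f):.6g} mg/kg/d")
        print(f"  check dermal DEHP @ 0.01% w/w: {anchor:.6g} mg/kg/d")


if __name__ == "__main__":
    main()
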