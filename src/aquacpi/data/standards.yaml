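# Reuse standards for treated effluent: the eleven routinely monitored
# parameters and the objective limits per reuse scenario.
# S1 restricted irrigation, S2 unrestricted irrigation (existing KSA
# standards); S3 fishery + livestock drinking, S4 fishery + recreation
# (recommended targets for continuous performance improvement).
parameters:
  - {code: TDS,   name: Total dissolved solids,      unit: mg/L,       group: physical}
  - {code: TSS,   name: Total suspended solids,      unit: mg/L,       group: physical}
  - {code: pH,    name: pH,                          unit: "-",        group: chemical}
  - {code: BOD5,  name: Biochemical oxygen demand,   unit: mg/L,       group: chemical}
  - {code: COD,   name: Chemical oxygen demand,      unit: mg/L,       group: chemical}
  - {code: NH3-N, name: Ammonia nitrogen,            unit: mg/L,       group: chemical}
  - {code: NO3-N, name: Nitrate nitrogen,            unit: mg/L,       group: chemical}
  - {code: PO4-P, name: Phosphates,                  unit: mg/L,       group: chemical}
  - {code: Cl2,   name: Residual chlorine,           unit: mg/L,       group: chemical}
  - {code: TC,    name: Total coliforms,             unit: MPN/100mL,  group: biological}
  - {code: FC,    name: Fecal coliforms,             unit: MPN/100mL,  group: biological}

scenarios:
  - scenario_id: S1
    description: Existing scenario for reuse of wastewater for restricted irrigation (RI)
    objectives:
      TDS:   {bound_type: upper, high: 2500}
      TSS:   {bound_type: upper, high: 40}
      pH:    {bound_type: range, low: 6.0, high: 8.4}
      BOD5:  {bound_type: upper, high: 40}
      COD:   {bound_type: upper, high: 50}
      NH3-N: {bound_type: upper, high: 5}
      NO3-N: {bound_type: upper, high: 10}
      PO4-P: {bound_type: upper, high: 10}
      Cl2:   {bound_type: range, low: 0.2, high: 0.5}
      TC:    {bound_type: upper, high: 1000}
      FC:    {bound_type: upper, high: 1000}
  - scenario_id: S2
    description: Existing scenario for reuse applications for unrestricted irrigation (URI)
    objectives:
      TDS:   {bound_type: upper, high: 2000}
      TSS:   {bound_type: upper, high: 10}
      pH:    {bound_type: range, low: 6.0, high: 8.4}
      BOD5:  {bound_type: upper, high: 10}
      COD:   {bound_type: upper, high: 50}
      NH3-N: {bound_type: upper, high: 5}
      NO3-N: {bound_type: upper, high: 10}
      PO4-P: {bound_type: upper, high: 10}
      Cl2:   {bound_type: range, low: 0.2, high: 0.5}
      TC:    {bound_type: upper, high: 10}
      FC:    {bound_type: upper, high: 2.2}
  - scenario_id: S3
    description: Cycle 1 of continuous improvement for wastewater reuse for fishery and livestock drinking (FLD)
    objectives:
      TDS:   {bound_type: upper, high: 1500}
      TSS:   {bound_type: upper, high: 5}
      pH:    {bound_type: range, low: 6.5, high: 8.5}
      BOD5:  {bound_type: upper, high: 5}
      COD:   {bound_type: upper, high: 40}
      NH3-N: {bound_type: upper, high: 0.9}
      NO3-N: {bound_type: upper, high: 10}
      PO4-P: {bound_type: upper, high: 2}
      Cl2:   {bound_type: range, low: 0.2, high: 0.5}
      TC:    {bound_type: upper, high: 2.2}
      FC:    {bound_type: absent}
  - scenario_id: S4
    description: Cycle 2 for continuous improvement for wastewater reuse for fishery and recreation uses (FR)
    objectives:
      TDS:   {bound_type: upper, high: 450}
      TSS:   {bound_type: upper, high: 5}
      pH:    {bound_type: range, low: 6.5, high: 8.0}
      BOD5:  {bound_type: upper, high: 3}
      COD:   {bound_type: upper, high: 25}
      NH3-N: {bound_type: upper, high: 0.3}
      NO3-N: {bound_type: upper, high: 7}
      PO4-P: {bound_type: upper, high: 2}
      Cl2:   {bound_type: range, low: 0.2, high: 0.5}
      TC:    {bound_type: upper, high: 2.2}
      FC:    {bound_type: absent}
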