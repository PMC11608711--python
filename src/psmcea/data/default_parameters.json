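{
  "schema_version": 1,
  "currency": "USD 2024",
  "parameters": [
    {"name": "Cost_best supportive care", "mean": 3835.0, "sd": 442.8, "low": 3068, "high": 4602, "distribution": "gamma"},
    {"name": "Cost_end-of-life care", "mean": 12797.9, "sd": 1477.8, "low": 10238, "high": 15358, "distribution": "gamma"},
    {"name": "Follow-up cost", "mean": 547.86, "sd": 63.3, "low": 438, "high": 657, "distribution": "gamma"},
    {"name": "Administration cost", "mean": 174.0, "sd": 20.1, "low": 139, "high": 209, "distribution": "gamma"},
    {"name": "Cost_paclitaxel_1 mg", "mean": 0.1, "sd": 0, "low": 0.08, "high": 0.12, "distribution": "gamma"},
    {"name": "Cost_bevacizumab_10 mg", "mean": 72.5, "sd": 8.4, "low": 58, "high": 87, "distribution": "gamma"},
    {"name": "Cost_cisplatin_10 mg", "mean": 3.7, "sd": 0.4, "low": 3, "high": 5, "distribution": "gamma"},
    {"name": "Cost_carboplatin_50 mg", "mean": 3.7, "sd": 0.4, "low": 3, "high": 4, "distribution": "gamma"},
    {"name": "Cost_pembrolizumab_1 mg", "mean": 56.7, "sd": 6.5, "low": 45, "high": 68, "distribution": "gamma"},
    {"name": "Cost_atezolizumab_10 mg", "mean": 85.8, "sd": 9.9, "low": 69, "high": 103, "distribution": "gamma"},
    {"name": "Cost_peripheral or sensory neuropathy", "mean": 9227.1, "sd": 1065.4, "low": 7382, "high": 11072, "distribution": "gamma"},
    {"name": "Cost_asthenia", "mean": 9860.3, "sd": 1138.5, "low": 7888, "high": 11832, "distribution": "gamma"},
    {"name": "Cost_anaemia", "mean": 15960.2, "sd": 1842.9, "low": 12768, "high": 19152, "distribution": "gamma"},
    {"name": "Cost_neutropenia", "mean": 11562.1, "sd": 1335.1, "low": 9250, "high": 13874, "distribution": "gamma"},
    {"name": "Cost_hypertension", "mean": 2814.5, "sd": 324.9, "low": 2251, "high": 3377, "distribution": "gamma"},
    {"name": "Cost_proteinuria", "mean": 5799.3, "sd": 669.6, "low": 4639, "high": 6959, "distribution": "gamma"},
    {"name": "Cost_thrombocytopenia", "mean": 14056.1, "sd": 1623.0, "low": 11245, "high": 16867, "distribution": "gamma"},
    {"name": "Cost_urinary tract infection", "mean": 9149.0, "sd": 1056.4, "low": 7319, "high": 10979, "distribution": "gamma"},
    {"name": "Cost_platelet count decreased", "mean": 15954.1, "sd": 1842.2, "low": 12763, "high": 19145, "distribution": "gamma"},
    {"name": "Cost_white blood cell count decreased", "mean": 10782.8, "sd": 1245.0, "low": 8626, "high": 12938, "distribution": "gamma"},
    {"name": "Cost_neutrophil count decreased", "mean": 16625.7, "sd": 1919.7, "low": 13300, "high": 19950, "distribution": "gamma"},
    {"name": "Cost_febrile neutropenia", "mean": 17597.1, "sd": 2031.9, "low": 14078, "high": 21116, "distribution": "gamma"},
    {"name": "Subsequent active treatment cost", "mean": 208.9, "sd": 1.3, "low": 207, "high": 211, "distribution": "gamma"},
    {"name": "Utility_PFS", "mean": 0.817, "sd": 0.1, "low": 0.65, "high": 0.98, "distribution": "beta"},
    {"name": "Utility_PD", "mean": 0.779, "sd": 0.1, "low": 0.62, "high": 0.93, "distribution": "beta"},
    {"name": "Disu_SAE", "mean": 0.28, "sd": 0, "low": 0.22, "high": 0.34, "distribution": "beta"},
    {"name": "SAE_ABC_peripheral or sensory neuropathy", "mean": 0.07, "sd": 0, "low": 0.06, "high": 0.08, "distribution": "beta"},
    {"name": "SAE_ABC_asthenia", "mean": 0.11, "sd": 0, "low": 0.09, "high": 0.13, "distribution": "beta"},
    {"name": "SAE_ABC_anaemia", "mean": 0.14, "sd": 0, "low": 0.11, "high": 0.17, "distribution": "beta"},
    {"name": "SAE_ABC_neutropenia", "mean": 0.18, "sd": 0, "low": 0.14, "high": 0.22, "distribution": "beta"},
    {"name": "SAE_ABC_hypertension", "mean": 0.18, "sd": 0, "low": 0.14, "high": 0.22, "distribution": "beta"},
    {"name": "SAE_ABC_proteinuria", "mean": 0.06, "sd": 0, "low": 0.05, "high": 0.07, "distribution": "beta"},
    {"name": "SAE_ABC_thrombocytopenia", "mean": 0.05, "sd": 0, "low": 0.04, "high": 0.06, "distribution": "beta"},
    {"name": "SAE_BC_asthenia", "mean": 0.09, "sd": 0, "low": 0.07, "high": 0.11, "distribution": "beta"},
    {"name": "SAE_BC_anaemia", "mean": 0.07, "sd": 0, "low": 0.06, "high": 0.08, "distribution": "beta"},
    {"name": "SAE_BC_neutropenia", "mean": 0.25, "sd": 0, "low": 0.2, "high": 0.3, "distribution": "beta"},
    {"name": "SAE_BC_hypertension", "mean": 0.16, "sd": 0, "low": 0.13, "high": 0.19, "distribution": "beta"},
    {"name": "SAE_BC_thrombocytopenia", "mean": 0.06, "sd": 0, "low": 0.05, "high": 0.07, "distribution": "beta"},
    {"name": "SAE_PBC_anaemia", "mean": 0.303, "sd": 0, "low": 0.24, "high": 0.36, "distribution": "beta"},
    {"name": "SAE_PBC_neutropenia", "mean": 0.124, "sd": 0, "low": 0.1, "high": 0.15, "distribution": "beta"},
    {"name": "SAE_PBC_hypertension", "mean": 0.094, "sd": 0, "low": 0.08, "high": 0.11, "distribution": "beta"},
    {"name": "SAE_PBC_thrombocytopenia", "mean": 0.075, "sd": 0, "low": 0.06, "high": 0.09, "distribution": "beta"},
    {"name": "SAE_PBC_urinary tract infection", "mean": 0.088, "sd": 0, "low": 0.07, "high": 0.11, "distribution": "beta"},
    {"name": "SAE_PBC_platelet count decreased", "mean": 0.068, "sd": 0, "low": 0.05, "high": 0.08, "distribution": "beta"},
    {"name": "SAE_PBC_white blood cell count decreased", "mean": 0.068, "sd": 0, "low": 0.05, "high": 0.08, "distribution": "beta"},
    {"name": "SAE_PBC_neutrophil count decreased", "mean": 0.13, "sd": 0, "low": 0.1, "high": 0.16, "distribution": "beta"},
    {"name": "SAE_PBC_febrile neutropenia", "mean": 0.072, "sd": 0, "low": 0.06, "high": 0.09, "distribution": "beta"},
    {"name": "SAE_ABC", "mean": 0.79, "sd": 0.1, "low": 0.63, "high": 0.95, "distribution": "beta"},
    {"name": "SAE_BC", "mean": 0.75, "sd": 0.1, "low": 0.6, "high": 0.9, "distribution": "beta"},
    {"name": "SAE_PBC", "mean": 0.818, "sd": 0.1, "low": 0.65, "high": 0.98, "distribution": "beta"},
    {"name": "HR_OS_PEM VS C", "mean": 0.63, "sd": 0.1, "low": 0.47, "high": 0.87, "distribution": "lognormal"},
    {"name": "HR_PFS_PEM VS C", "mean": 0.61, "sd": 0.1, "low": 0.47, "high": 0.79, "distribution": "lognormal"},
    {"name": "Subsequent active treatment_ABC", "mean": 0.54, "sd": 0.1, "low": 0.43, "high": 0.65, "distribution": "beta"},
    {"name": "Subsequent active treatment_PBC", "mean": 0.54, "sd": 0.1, "low": 0.43, "high": 0.65, "distribution": "beta"},
    {"name": "Subsequent active treatment_BC", "mean": 0.58, "sd": 0.1, "low": 0.46, "high": 0.7, "distribution": "beta"},
    {"name": "Average weight of the US female", "mean": 77.5, "sd": 0, "low": 77.5, "high": 77.5, "distribution": "fixed"},
    {"name": "Average body surface of the US female", "mean": 1.86, "sd": 0, "low": 1.86, "high": 1.86, "distribution": "fixed"},
    {"name": "Discount", "mean": 0.03, "sd": 0, "low": 0, "high": 0.08, "distribution": "beta"}
  ]
}
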