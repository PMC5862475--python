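compound,tissue_administration,auc_observed,auc_predicted,auc_optimized,pct_error_predicted,pct_error_optimized,scenario_id,compartment
inulin,Venous Blood (40 mg/kg)/i.v.,842.36,994.63,,15.31,,inulin_iv_40,venous_plasma
inulin,Venous Blood (60 mg/kg)/i.v.,1345.61,1491.95,,9.81,,inulin_iv_60,venous_plasma
inulin,Plasma/i.v.,6901.24,9383.03,7564.91,26.45,8.77,inulin_iv_200,venous_plasma
inulin,Lung/i.v.,1071.31,3643.40,1186.67,70.60,9.72,inulin_iv_200,lung
inulin,Skin/i.v.,2438.59,1435.94,2242.76,69.83,8.73,inulin_iv_200,skin
inulin,Bone/i.v.,660.24,941.45,760.29,29.87,13.16,inulin_iv_200,bone
inulin,Heart/i.v.,873.24,1045.38,819.07,16.47,6.61,inulin_iv_200,heart
inulin,Muscle/i.v.,620.97,1090.23,884.54,43.04,29.80,inulin_iv_200,muscle
caffeine,Venous Blood/i.v.,5432.82,7747.60,5739.40,29.88,5.34,caffeine_iv_4,venous_plasma
theophylline,Venous Blood/i.v.,23871.43,63755.93,27257.72,62.56,12.42,theophylline_iv_12,venous_plasma
theophylline,Venous Blood/i.v.,54651.84,57080.23,54084.85,4.25,1.05,theophylline_iv_15,venous_plasma
theophylline (PO),Venous Blood/Conventional Tablet,217832.06,86553.63,192065.78,151.67,13.42,theophylline_po_200,venous_plasma
paracetamol (PO),Venous Blood/Solution,2279.80,1836.71,2372.61,24.12,3.91,paracetamol_po_solution,venous_plasma
paracetamol (PO),Venous Blood/Rapid Tablet,1712.76,1958.72,1581.04,12.56,8.33,paracetamol_po_rapid,venous_plasma
paracetamol (PO),Venous Blood/Conventional Tablet,2225.68,401.05,1335.17,454.96,66.70,paracetamol_po_conventional,venous_plasma
acyclovir (PO),Venous Blood/Solution,6469.00,9089.22,7630.12,28.83,15.22,acyclovir_po_300,venous_plasma
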