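# Rule base of the packaged mini type-2-diabetes model.
# This is an explicit class-level reconstruction wired from the published
# mechanisms of the 22 drugs; it makes no claim to completeness.
#
# Disease process: chronic insulin resistance drives circulation glucose up.
# The disease rule is persistent, so it competes with drug-induced rules at
# every step until the resistance flag is cleared.
Cell,muscle,flag,insulin_resistance,present -> Organ,circulation,metabolite,glucose,up @id=T2D1 @disease @persistent @src=curated:insulin-resistance-hyperglycemia

# Base physiology: a surge of circulating insulin restores insulin
# sensitivity in muscle (class-level simplification).
Organ,circulation,hormone,insulin,up -> Cell,muscle,flag,insulin_resistance,absent @id=PHYS1 @src=curated:insulin-signalling

# --- biguanide (metformin): hepatic AMPK activation ---
Drug,metformin,presence,status,present -> Cell,hepatocyte,gene,PRKAB1,up @id=MET1 @src=curated:metformin-AMPK
Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,AGRP,up @id=MET2 @src=curated:AMPK-AGRP
Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,PEPCK,down @id=MET3 @src=curated:AMPK-represses-gluconeogenesis
Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,G6PC,down @id=MET4 @src=curated:AMPK-represses-gluconeogenesis
Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,GLUT4,up @id=MET5 @src=curated:AMPK-glucose-uptake
Cell,hepatocyte,gene,PRKAB1,up -> Cell,muscle,flag,insulin_resistance,absent @id=MET6 @src=curated:AMPK-insulin-sensitivity
Cell,hepatocyte,gene,PEPCK,down & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=MET7 @persistent @src=curated:less-gluconeogenesis
Cell,hepatocyte,gene,G6PC,down & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=MET8 @persistent @src=curated:less-glucose-release
Cell,hepatocyte,gene,GLUT4,up & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=MET9 @persistent @src=curated:hepatic-uptake

# --- thiazolidinedione targeting adipocyte (rosiglitazone) ---
Drug,rosiglitazone,presence,status,present -> Cell,adipocyte,gene,PPARG,up @id=ROS1 @src=curated:TZD-PPARg
Cell,adipocyte,gene,PPARG,up -> Cell,adipocyte,gene,GLUT4,up @id=ADI1 @src=curated:PPARg-GLUT4
Cell,adipocyte,gene,PPARG,up -> Cell,muscle,flag,insulin_resistance,absent @id=ADI2 @src=curated:sensitizer
Cell,adipocyte,gene,GLUT4,up & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=ADI3 @persistent @src=curated:adipose-uptake

# --- thiazolidinediones targeting muscle (pioglitazone, troglitazone) ---
Drug,pioglitazone,presence,status,present -> Cell,muscle,gene,GLUT4,up @id=PIO1 @src=curated:TZD-muscle
Drug,troglitazone,presence,status,present -> Cell,muscle,gene,GLUT4,up @id=TRO1 @src=curated:TZD-muscle
Cell,muscle,gene,GLUT4,up -> Cell,muscle,flag,insulin_resistance,absent @id=MUS1 @src=curated:sensitizer
Cell,muscle,gene,GLUT4,up & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=MUS2 @persistent @src=curated:muscle-uptake

# --- insulin secretagogues and incretin-axis drugs (beta-cell) ---
# Each closes the beta-cell KATP channel (directly for sulfonylureas and
# glinides, via the incretin axis for GLP-1 agonists and DPP-4 inhibitors);
# a closed channel sustains insulin secretion while glucose is elevated.
Drug,saxagliptin,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC01 @src=curated:incretin-axis
Drug,sitagliptin,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC02 @src=curated:incretin-axis
Drug,vildagliptin,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC03 @src=curated:incretin-axis
Drug,exenatide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC04 @src=curated:GLP1-agonist
Drug,liraglutide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC05 @src=curated:GLP1-agonist
Drug,mitiglinide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC06 @src=curated:glinide
Drug,nateglinide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC07 @src=curated:glinide
Drug,repaglinide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC08 @src=curated:glinide
Drug,chlorpropamide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC09 @src=curated:sulfonylurea
Drug,glipizide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC10 @src=curated:sulfonylurea
Drug,gliquidone,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC11 @src=curated:sulfonylurea
Drug,tolbutamide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC12 @src=curated:sulfonylurea
Drug,glimepiride,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC13 @src=curated:sulfonylurea
Drug,glyburide,presence,status,present -> Cell,beta-cell,channel,KATP,close @id=SEC14 @src=curated:sulfonylurea
Cell,beta-cell,channel,KATP,close & Organ,circulation,metabolite,glucose,up -> Organ,circulation,hormone,insulin,up @id=BET1 @persistent @src=curated:insulin-secretion
Organ,circulation,hormone,insulin,up & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=INS1 @persistent @src=curated:insulin-lowers-glucose

# --- glucose-appearance reducers (alpha-glucosidase inhibitors, amylin) ---
Drug,miglitol,presence,status,present -> Cell,gut,gene,alpha_glucosidase,down @id=GUT01 @src=curated:AGI
Drug,voglibose,presence,status,present -> Cell,gut,gene,alpha_glucosidase,down @id=GUT02 @src=curated:AGI
Drug,acarbose,presence,status,present -> Cell,gut,gene,alpha_glucosidase,down @id=GUT03 @src=curated:AGI
Drug,pramlintide,presence,status,present -> Cell,gut,gene,alpha_glucosidase,down @id=GUT04 @src=curated:amylin-slows-absorption
Cell,gut,gene,alpha_glucosidase,down -> Cell,muscle,flag,insulin_resistance,absent @id=GUT05 @src=curated:reduced-postprandial-load
Cell,gut,gene,alpha_glucosidase,down & Organ,circulation,metabolite,glucose,up -> Organ,circulation,metabolite,glucose,down @id=GUT06 @persistent @src=curated:slower-absorption
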