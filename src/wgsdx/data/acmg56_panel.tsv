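gene	inheritance	condition
BRCA1	AD	Hereditary breast and ovarian cancer
BRCA2	AD	Hereditary breast and ovarian cancer
TP53	AD	Li-Fraumeni syndrome
STK11	AD	Peutz-Jeghers syndrome
MLH1	AD	Lynch syndrome
MSH2	AD	Lynch syndrome
MSH6	AD	Lynch syndrome
PMS2	AD	Lynch syndrome
APC	AD	Familial adenomatous polyposis
MUTYH	AR	MYH-associated polyposis
VHL	AD	Von Hippel-Lindau syndrome
MEN1	AD	Multiple endocrine neoplasia type 1
RET	AD	Multiple endocrine neoplasia type 2
PTEN	AD	PTEN hamartoma tumour syndrome
RB1	AD	Retinoblastoma
SDHD	AD	Hereditary paraganglioma-pheochromocytoma
SDHAF2	AD	Hereditary paraganglioma-pheochromocytoma
SDHC	AD	Hereditary paraganglioma-pheochromocytoma
SDHB	AD	Hereditary paraganglioma-pheochromocytoma
TSC1	AD	Tuberous sclerosis complex
TSC2	AD	Tuberous sclerosis complex
WT1	AD	WT1-related Wilms tumour
NF2	AD	Neurofibromatosis type 2
COL3A1	AD	Ehlers-Danlos syndrome vascular type
FBN1	AD	Marfan syndrome
TGFBR1	AD	Loeys-Dietz syndrome
TGFBR2	AD	Loeys-Dietz syndrome
SMAD3	AD	Loeys-Dietz syndrome
ACTA2	AD	Familial thoracic aortic aneurysm and dissection
MYLK	AD	Familial thoracic aortic aneurysm and dissection
MYH11	AD	Familial thoracic aortic aneurysm and dissection
MYBPC3	AD	Hypertrophic cardiomyopathy
MYH7	AD	Hypertrophic cardiomyopathy
TNNT2	AD	Hypertrophic cardiomyopathy
TNNI3	AD	Hypertrophic cardiomyopathy
TPM1	AD	Hypertrophic cardiomyopathy
MYL3	AD	Hypertrophic cardiomyopathy
ACTC1	AD	Hypertrophic cardiomyopathy
PRKAG2	AD	Hypertrophic cardiomyopathy
GLA	AD	Fabry disease
MYL2	AD	Hypertrophic cardiomyopathy
LMNA	AD	Dilated cardiomyopathy
RYR2	AD	Catecholaminergic polymorphic ventricular tachycardia
PKP2	AD	Arrhythmogenic right ventricular cardiomyopathy
DSP	AD	Arrhythmogenic right ventricular cardiomyopathy
DSC2	AD	Arrhythmogenic right ventricular cardiomyopathy
TMEM43	AD	Arrhythmogenic right ventricular cardiomyopathy
DSG2	AD	Arrhythmogenic right ventricular cardiomyopathy
KCNQ1	AD	Romano-Ward long QT syndrome
KCNH2	AD	Romano-Ward long QT syndrome
SCN5A	AD/AR	Romano-Ward long QT / Brugada syndrome
LDLR	AD	Familial hypercholesterolaemia
APOB	AD	Familial hypercholesterolaemia
PCSK9	AD	Familial hypercholesterolaemia
RYR1	AD	Malignant hyperthermia susceptibility
CACNA1S	AD	Malignant hyperthermia susceptibility
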