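"""Built-in list of valid small-molecule SMILES used by the synthetic generator.

Canonical RDKit SMILES of well-known approved drugs; the synthetic knowledge
graph assigns these to drug nodes so that fingerprint featurization always
operates on chemically valid input.
"""

DRUG_SMILES: list[str] = [
    'CC(=O)Oc1ccccc1C(=O)O',  # aspirin
    'CC(=O)Nc1ccc(O)cc1',  # paracetamol
    'CC(C)Cc1ccc(C(C)C(=O)O)cc1',  # ibuprofen
    'Cn1c(=O)c2c(ncn2C)n(C)c1=O',  # caffeine
    'COc1ccc2cc(C(C)C(=O)O)ccc2c1',  # naproxen
    'O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl',  # diclofenac
    'CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1',  # ketoprofen
    'COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1',  # indomethacin
    'Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1',  # celecoxib
    'CN1C(C(=O)Nc2ccccn2)=CC(=O)c2ccccc2S1(=O)=O',  # piroxicam
    'Cc1cnc(NC(=O)C2=C(O)c3ccccc3S(=O)(=O)N2C)s1',  # meloxicam
    'CC(=O)Nc1nnc(S(N)(=O)=O)s1',  # acetazolamide
    'NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O',  # hydrochlorothiazide
    'NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl',  # furosemide
    'CC(C)NCC(O)COc1ccc(CC(N)=O)cc1',  # atenolol
    'COCCc1ccc(OCC(O)CNC(C)C)cc1',  # metoprolol
    'CC(C)NCC(O)COc1cccc2ccccc12',  # propranolol
    'COc1ccccc1OCCNCC(O)COc1cccc2[nH]c3ccccc3c12',  # carvedilol
    'CC(CCc1ccccc1)NCC(O)c1ccc(O)c(C(N)=O)c1',  # labetalol
    'CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl',  # amlodipine
    'COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]',  # nifedipine
    'COc1ccc(CCN(C)CCCC(C#N)(c2ccc(OC)c(OC)c2)C(C)C)cc1OC',  # verapamil
    'COc1ccc(C2Sc3ccccc3N(CCN(C)C)C(=O)C2OC(C)=O)cc1',  # diltiazem
    'CC(CS)C(=O)N1CCCC1C(=O)O',  # captopril
    'CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O',  # enalapril
    'NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O',  # lisinopril
    'CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1',  # losartan
    'CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(=O)O)C(C)C',  # valsartan
    'CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O',  # warfarin
    'COC(=O)C(c1ccccc1Cl)N1CCc2sccc2C1',  # clopidogrel
    'CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21',  # simvastatin
    'CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O',  # atorvastatin
    'CCC(C)C(=O)OC1CC(O)C=C2C=CC(C)C(CCC(O)CC(O)CC(=O)O)C21',  # pravastatin
    'Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1',  # gemfibrozil
    'CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1',  # fenofibrate
    'CN(C)C(=N)NC(=N)N',  # metformin
    'Cc1cnc(C(=O)NCCc2ccc(S(=O)(=O)NC(=O)NC3CCCCC3)cc2)cn1',  # glipizide
    'COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1',  # glibenclamide
    'CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1',  # pioglitazone
    'CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1',  # rosiglitazone
    'COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1',  # omeprazole
    'Cc1c(OCC(F)(F)F)ccnc1CS(=O)c1nc2ccccc2[nH]1',  # lansoprazole
    'CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1',  # ranitidine
    'CN=C(NC#N)NCCSCc1nc[nH]c1C',  # cimetidine
    'N=C(N)c1nc(CSCCC(N)=NS(N)(=O)=O)cs1',  # famotidine
    'Cc1nccn1CC1CCc2c(c3ccccc3n2C)C1=O',  # ondansetron
    'CCN(CC)CCNC(=O)c1cc(Cl)c(N)cc1OC',  # metoclopramide
    'CN(C)C(=O)C(CCN1CCC(O)(c2ccc(Cl)cc2)CC1)(c1ccccc1)c1ccccc1',  # loperamide
    'CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21',  # sertraline
    'CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1',  # fluoxetine
    'Fc1ccc(C2CCNCC2COc2ccc3c(c2)OCO3)cc1',  # paroxetine
    'CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21',  # citalopram
    'COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1',  # venlafaxine
    'CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1',  # bupropion
    'CN(C)CCC=C1c2ccccc2CCc2ccccc21',  # amitriptyline
    'CN(C)CCCN1c2ccccc2CCc2ccccc21',  # imipramine
    'CNCCC=C1c2ccccc2CCc2ccccc21',  # nortriptyline
    'CNCCC(Oc1cccc2ccccc12)c1cccs1',  # duloxetine
    'O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12',  # trazodone
    'CN1CCN2c3ccccc3Cc3ccccc3C2C1',  # mirtazapine
    'O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1',  # haloperidol
    'Cc1nc2n(c(=O)c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2',  # risperidone
    'Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1',  # olanzapine
    'OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1',  # quetiapine
    'O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1',  # aripiprazole
    'CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21',  # diazepam
    'O=C1Nc2ccc(Cl)cc2C(c2ccccc2Cl)=NC1O',  # lorazepam
    'Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2',  # alprazolam
    'Cc1ncc2n1-c1ccc(Cl)cc1C(c1ccccc1F)=NC2',  # midazolam
    'Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1',  # zolpidem
    'O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1',  # phenytoin
    'NC(=O)N1c2ccccc2C=Cc2ccccc21',  # carbamazepine
    'Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1',  # lamotrigine
    'CCCC(CCC)C(=O)O',  # valproate
    'NCC1(CC(=O)O)CCCCC1',  # gabapentin
    'CC1(C)OC2COC3(COS(N)(=O)=O)OC(C)(C)OC3C2O1',  # topiramate
    'CCC(C(N)=O)N1CCCC1=O',  # levetiracetam
    'NC(Cc1ccc(O)c(O)c1)C(=O)O',  # levodopa
    'C#CCN(C)C(C)Cc1ccccc1',  # selegiline
    'CCCNC1CCc2nc(N)sc2C1',  # pramipexole
    'CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5',  # morphine
    'COc1ccc2c3c1OC1C(O)C=CC4C(C2)N(C)CCC341',  # codeine
    'COc1cccc(C2(O)CCCCC2CN(C)C)c1',  # tramadol
    'CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1',  # fentanyl
    'CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1',  # methadone
    'C=CCN1CCC23c4c5ccc(O)c4OC2C(=O)CCC3(O)C1C5',  # naloxone
    'COc1ccc2c3c1OC1C(=O)CCC4N(C)CCC31C4(O)C2',  # oxycodone
    'CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O',  # amoxicillin
    'CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O',  # ampicillin
    'CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1',  # cephalexin
    'O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O',  # ciprofloxacin
    'CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23',  # levofloxacin
    'COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC',  # trimethoprim
    'Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1',  # sulfamethoxazole
    'Cc1ncc([N+](=O)[O-])n1CCO',  # metronidazole
    'NNC(=O)c1ccncc1',  # isoniazid
    'Cc1ccc(C)c(O)c1',  # rifampin-free-acid
    'OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F',  # fluconazole
    'CC(=O)N1CCN(c2ccc(OCC3COC(Cn4ccnc4)(c4ccc(Cl)cc4Cl)O3)cc2)CC1',  # ketoconazole
    'Nc1nc2c(ncn2COCCO)c(=O)[nH]1',  # acyclovir
    'Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O',  # zidovudine
    'CCOC(=O)C1=CC(OC(CC)CC)C(NC(C)=O)C(N)C1',  # oseltamivir
    'CC12C=CC(=O)C=C1CCC1C2C(=O)CC2(C)C1CCC2(O)C(=O)CO',  # prednisone
    'CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO',  # dexamethasone
    'CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO',  # hydrocortisone
    'CC12CCC3c4ccc(O)cc4CCC3C1CCC2O',  # estradiol
    'CC12CCC(=O)C=C1CCC1C2CCC2(C)C(O)CCC12',  # testosterone
    'CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1',  # tamoxifen
    'N#Cc1ccc(C(c2ccc(C#N)cc2)n2cncn2)cc1',  # letrozole
    'CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1',  # methotrexate
    'O=c1[nH]cc(F)c(=O)[nH]1',  # fluorouracil
    'Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1',  # imatinib
    'CCN(CC)CCNC(=O)c1c(C)[nH]c(C=C2C(=O)Nc3ccc(F)cc32)c1C',  # sunitinib
    'C#Cc1cccc(Nc2ncnc3cc(OCCOC)c(OCCOC)cc23)c1',  # erlotinib
    'COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1',  # gefitinib
    'O=c1[nH]cnc2[nH]ncc12',  # allopurinol
    'COC(=O)C1=CC2=CC(=O)C(OC)=CC2=C(c2ccc(OC)c(OC)c2OC)C1NC(C)=O',  # colchicine
    'CC(C)(C)NCC(O)c1ccc(O)c(CO)c1',  # salbutamol
    'OCc1cc(C(O)CNCCCCCCOCCCCc2ccccc2)ccc1O',  # salmeterol
    'Cn1c(=O)c2nc[nH]c2n(C)c1=O',  # theophylline
    'CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(C=Cc2ccc3ccc(Cl)cc3n2)c1',  # montelukast
    'O=C(O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1',  # cetirizine
    'CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1',  # loratadine
    'CN(C)CCOC(c1ccccc1)c1ccccc1',  # diphenhydramine
    'CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1',  # chlorpheniramine
    'CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12',  # sildenafil
    'CC(C)(C)NC(=O)C1CCC2C3CCC4NC(=O)C=CC4(C)C3CCC12C',  # finasteride
    'CCOc1ccccc1OCCNC(C)Cc1ccc(OC)c(S(N)(=O)=O)c1',  # tamsulosin
    'CC12CCC(O)CC1CCC1C2CC(O)C2(C)C(C3=CC(=O)OC3)CCC12O',  # digoxin-aglycone
    'NC(Cc1cc(I)c(Oc2cc(I)c(O)c(I)c2)c(I)c1)C(=O)O',  # levothyroxine
]
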