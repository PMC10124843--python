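code,system,category,outcome_class,ga_weeks,description
650,ICD9-DX,outcome,LB,,Normal delivery
V27.0,ICD9-DX,outcome,LB,,"Outcome of delivery, single liveborn"
V27.1,ICD9-DX,outcome,SB,,"Outcome of delivery, single stillborn"
656.41,ICD9-DX,outcome,SB,,"Intrauterine death, delivered"
V27.3,ICD9-DX,outcome,LB_SB,,"Outcome of delivery, twins, one liveborn and one stillborn"
634.91,ICD9-DX,outcome,SAB,,"Spontaneous abortion, complete"
632,ICD9-DX,outcome,SAB,,Missed abortion
635.92,ICD9-DX,outcome,IAB,,"Legally induced abortion, complete"
633.90,ICD9-DX,outcome,ECT,,Unspecified ectopic pregnancy
633.10,ICD9-DX,outcome,ECT,,Tubal pregnancy
637.91,ICD9-DX,outcome,UNKNOWN,,"Unspecified abortion, complete"
V27.9,ICD9-DX,outcome,UNKNOWN,,"Outcome of delivery, unspecified"
O80,ICD10-DX,outcome,LB,,Encounter for full-term uncomplicated delivery
Z37.0,ICD10-DX,outcome,LB,,Single live birth
Z37.1,ICD10-DX,outcome,SB,,Single stillbirth
O36.4XX0,ICD10-DX,outcome,SB,,Maternal care for intrauterine death
Z37.3,ICD10-DX,outcome,LB_SB,,"Twins, one liveborn and one stillborn"
O03.9,ICD10-DX,outcome,SAB,,Complete spontaneous abortion without complication
O02.1,ICD10-DX,outcome,SAB,,Missed abortion
O04.9,ICD10-DX,outcome,IAB,,Complete termination of pregnancy without complication
O00.90,ICD10-DX,outcome,ECT,,Unspecified ectopic pregnancy without intrauterine pregnancy
O00.10,ICD10-DX,outcome,ECT,,Tubal pregnancy without intrauterine pregnancy
Z37.9,ICD10-DX,outcome,UNKNOWN,,"Outcome of delivery, unspecified"
765,DRG,outcome,LB,,Cesarean section with CC/MCC
775,DRG,outcome,LB,,Vaginal delivery without complicating diagnoses
770,DRG,outcome,IAB,,"Abortion with D&C, aspiration curettage or hysterotomy"
779,DRG,outcome,SAB,,Abortion without D&C
777,DRG,outcome,ECT,,Ectopic pregnancy
59400,CPT,outcome,LB,,Routine obstetric care with vaginal delivery
59510,CPT,outcome,LB,,Routine obstetric care with cesarean delivery
74.99,ICD9-PX,outcome,LB,,"Cesarean section, unspecified"
59812,CPT,outcome,SAB,,"Treatment of incomplete abortion, surgical"
59820,CPT,outcome,SAB,,"Treatment of missed abortion, first trimester"
59840,CPT,outcome,IAB,,Induced abortion by dilation and curettage
59850,CPT,outcome,IAB,,Induced abortion by intra-amniotic injection
69.01,ICD9-PX,outcome,IAB,,D&C for termination of pregnancy
59120,CPT,outcome,ECT,,"Surgical treatment of ectopic pregnancy, salpingectomy/oophorectomy"
10E0XZZ,ICD10-PX,outcome,SB,,Delivery of products of conception (fixture assignment: stillbirth delivery procedure)
Z3A.08,ICD10-DX,direct_gestational_age,,8,8 weeks gestation of pregnancy
Z3A.09,ICD10-DX,direct_gestational_age,,9,9 weeks gestation of pregnancy
Z3A.10,ICD10-DX,direct_gestational_age,,10,10 weeks gestation of pregnancy
Z3A.11,ICD10-DX,direct_gestational_age,,11,11 weeks gestation of pregnancy
Z3A.12,ICD10-DX,direct_gestational_age,,12,12 weeks gestation of pregnancy
Z3A.13,ICD10-DX,direct_gestational_age,,13,13 weeks gestation of pregnancy
Z3A.14,ICD10-DX,direct_gestational_age,,14,14 weeks gestation of pregnancy
Z3A.15,ICD10-DX,direct_gestational_age,,15,15 weeks gestation of pregnancy
Z3A.16,ICD10-DX,direct_gestational_age,,16,16 weeks gestation of pregnancy
Z3A.17,ICD10-DX,direct_gestational_age,,17,17 weeks gestation of pregnancy
Z3A.18,ICD10-DX,direct_gestational_age,,18,18 weeks gestation of pregnancy
Z3A.19,ICD10-DX,direct_gestational_age,,19,19 weeks gestation of pregnancy
Z3A.20,ICD10-DX,direct_gestational_age,,20,20 weeks gestation of pregnancy
Z3A.21,ICD10-DX,direct_gestational_age,,21,21 weeks gestation of pregnancy
Z3A.22,ICD10-DX,direct_gestational_age,,22,22 weeks gestation of pregnancy
Z3A.23,ICD10-DX,direct_gestational_age,,23,23 weeks gestation of pregnancy
Z3A.24,ICD10-DX,direct_gestational_age,,24,24 weeks gestation of pregnancy
Z3A.25,ICD10-DX,direct_gestational_age,,25,25 weeks gestation of pregnancy
Z3A.26,ICD10-DX,direct_gestational_age,,26,26 weeks gestation of pregnancy
Z3A.27,ICD10-DX,direct_gestational_age,,27,27 weeks gestation of pregnancy
Z3A.28,ICD10-DX,direct_gestational_age,,28,28 weeks gestation of pregnancy
Z3A.29,ICD10-DX,direct_gestational_age,,29,29 weeks gestation of pregnancy
Z3A.30,ICD10-DX,direct_gestational_age,,30,30 weeks gestation of pregnancy
Z3A.31,ICD10-DX,direct_gestational_age,,31,31 weeks gestation of pregnancy
Z3A.32,ICD10-DX,direct_gestational_age,,32,32 weeks gestation of pregnancy
Z3A.33,ICD10-DX,direct_gestational_age,,33,33 weeks gestation of pregnancy
Z3A.34,ICD10-DX,direct_gestational_age,,34,34 weeks gestation of pregnancy
Z3A.35,ICD10-DX,direct_gestational_age,,35,35 weeks gestation of pregnancy
Z3A.36,ICD10-DX,direct_gestational_age,,36,36 weeks gestation of pregnancy
Z3A.37,ICD10-DX,direct_gestational_age,,37,37 weeks gestation of pregnancy
Z3A.38,ICD10-DX,direct_gestational_age,,38,38 weeks gestation of pregnancy
Z3A.39,ICD10-DX,direct_gestational_age,,39,39 weeks gestation of pregnancy
Z3A.40,ICD10-DX,direct_gestational_age,,40,40 weeks gestation of pregnancy
Z3A.41,ICD10-DX,direct_gestational_age,,41,41 weeks gestation of pregnancy
Z3A.42,ICD10-DX,direct_gestational_age,,42,42 weeks gestation of pregnancy
765.21,ICD9-DX,direct_gestational_age,,20,Less than 24 completed weeks of gestation (assigned single week)
765.22,ICD9-DX,direct_gestational_age,,24,24 completed weeks of gestation (assigned single week)
765.23,ICD9-DX,direct_gestational_age,,26,25-26 completed weeks of gestation (assigned single week)
765.24,ICD9-DX,direct_gestational_age,,28,27-28 completed weeks of gestation (assigned single week)
765.25,ICD9-DX,direct_gestational_age,,30,29-30 completed weeks of gestation (assigned single week)
765.26,ICD9-DX,direct_gestational_age,,32,31-32 completed weeks of gestation (assigned single week)
765.27,ICD9-DX,direct_gestational_age,,34,33-34 completed weeks of gestation (assigned single week)
765.28,ICD9-DX,direct_gestational_age,,36,35-36 completed weeks of gestation (assigned single week)
765.29,ICD9-DX,direct_gestational_age,,39,37 or more completed weeks of gestation (assigned single week)
V30.00,ICD9-DX,infant_birth_hospitalization,,,"Single liveborn, born in hospital, without cesarean"
V30.01,ICD9-DX,infant_birth_hospitalization,,,"Single liveborn, born in hospital, by cesarean"
V31.00,ICD9-DX,infant_birth_hospitalization,,,"Twin, mate liveborn, born in hospital"
Z38.00,ICD10-DX,infant_birth_hospitalization,,,"Single liveborn infant, delivered vaginally"
Z38.01,ICD10-DX,infant_birth_hospitalization,,,"Single liveborn infant, delivered by cesarean"
Z38.30,ICD10-DX,infant_birth_hospitalization,,,"Twin liveborn infant, delivered vaginally"
795,DRG,infant_birth_hospitalization,,,Normal newborn
765.10,ICD9-DX,preterm_prolonged,,35,"Other preterm infant, unspecified weight"
644.21,ICD9-DX,preterm_prolonged,,35,"Early onset of delivery, delivered"
766.22,ICD9-DX,preterm_prolonged,,42,Prolonged gestation of infant
645.11,ICD9-DX,preterm_prolonged,,42,"Post-term pregnancy, delivered"
P07.30,ICD10-DX,preterm_prolonged,,35,"Preterm newborn, unspecified weeks of gestation"
O60.14X0,ICD10-DX,preterm_prolonged,,35,Preterm labor third trimester with preterm delivery
P08.21,ICD10-DX,preterm_prolonged,,42,Post-term newborn
O48.0,ICD10-DX,preterm_prolonged,,42,Post-term pregnancy
59120,CPT,ectopic_verification,,,Surgical treatment of ectopic pregnancy (also an ectopic outcome code)
59121,CPT,ectopic_verification,,,Surgical treatment of ectopic pregnancy without salpingectomy
59150,CPT,ectopic_verification,,,Laparoscopic treatment of ectopic pregnancy
66.62,ICD9-PX,ectopic_verification,,,Salpingectomy with removal of tubal pregnancy
J9250,HCPCS,methotrexate,,,"Methotrexate sodium, 5 mg"
J9260,HCPCS,methotrexate,,,"Methotrexate sodium, 50 mg"
58974,CPT,fertility_procedure,,,"Embryo transfer, intrauterine"
58322,CPT,fertility_procedure,,,"Artificial insemination, intracervical/intrauterine"
S4037,HCPCS,fertility_procedure,,,Cryopreserved embryo transfer
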