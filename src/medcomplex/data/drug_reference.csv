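pzn,brand_name,active_ingredients,form_class,device_subtype,prescription_only,strength_mg,component_strengths_mg,divisible,palatability_issue,requires_technique_training,self_measurement_linked,orodispersible,extended_release,equivalence_group
04773414,AmloBene 5,amlodipine,solid_oral,,true,5,,true,false,false,false,false,false,amlodipine_oral
04773415,AmloBene 10,amlodipine,solid_oral,,true,10,,true,false,false,false,false,false,amlodipine_oral
01000011,Ramilich 5,ramipril,solid_oral,,true,5,,true,false,false,false,false,false,ramipril_oral
01000012,Ramilich 10,ramipril,solid_oral,,true,10,,true,false,false,false,false,false,ramipril_oral
01000021,Theo 100,theophylline,solid_oral,,true,100,,false,false,false,false,false,false,theophylline_oral
01000022,Theo retard 300,theophylline,solid_oral,,true,300,,false,false,false,false,false,true,theophylline_oral
01000031,Furo 40,furosemide,solid_oral,,true,40,,true,false,false,false,false,false,furosemide_oral
01000032,Furo Loesung 40,furosemide,liquid_oral,liquid_measuring_device,true,40,,false,false,false,false,false,false,furosemide_oral
01000041,Risperi 1,risperidone,solid_oral,,true,1,,true,false,false,false,false,false,risperidone_oral
01000042,Risperi Schmelz 1,risperidone,solid_oral,,true,1,,false,false,false,false,true,false,risperidone_oral
01000051,Insulatest Vial,insulin glargine,injection,non_prefilled_injector,true,100,,false,false,false,false,false,false,insulin_basal
01000052,Insulatest Pen,insulin glargine,injection,prefilled_injector,true,100,,false,false,false,false,false,false,insulin_basal
01000061,Valsa 160,valsartan,solid_oral,,true,160,,true,false,false,false,false,false,valsartan_oral
01000062,HCT Dura 12.5,hydrochlorothiazide,solid_oral,,true,12.5,,true,false,false,false,false,false,hct_oral
01000063,ValsaComp 160/12.5,valsartan+hydrochlorothiazide,solid_oral,,true,,160+12.5,false,false,false,false,false,false,valsartan_hct_fdc
01000071,SalbuMist,salbutamol,inhaler,metered_dose_inhaler,true,0.1,,false,false,false,false,false,false,salbutamol_inh
01000072,BudeElpen,budesonide,inhaler,elpenhaler,true,0.2,,false,false,false,false,false,false,budesonide_inh
01000073,IpraNeb,ipratropium,inhaler,nebuliser,true,0.25,,false,false,false,false,false,false,ipratropium_inh
01000074,FormoCaps,formoterol,inhaler,capsule_inhaler,true,0.012,,false,false,false,false,false,false,formoterol_inh
01000075,BecloHaler,beclometasone,inhaler,other_inhaler,true,0.1,,false,false,false,false,false,false,beclometasone_inh
01000081,LataVision,latanoprost,ophthalmic,eye_drops,true,0.005,,false,false,false,false,false,false,latanoprost_eye
01000082,DexaVision Salbe,dexamethasone,ophthalmic,eye_ointment,true,1,,false,false,false,false,false,false,dexamethasone_eye
01000091,MomeNasal,mometasone,nasal,,true,0.05,,false,false,false,false,false,false,mometasone_nasal
01000092,XyloNasal,xylometazoline,nasal,,false,0.1,,false,false,false,false,false,false,xylometazoline_nasal
01000101,NystaLutsch,nystatin,oropharyngeal_solid,,true,100,,false,false,false,false,false,false,nystatin_oro
01000102,ChlorheMund,chlorhexidine,oropharyngeal_liquid,,false,10,,false,false,false,false,false,false,chlorhexidine_oro
01000111,FentaPatch 25,fentanyl,transdermal_patch,,true,2.1,,false,false,false,false,false,false,fentanyl_td
01000121,BisacoSupp 10,bisacodyl,rectal,,false,10,,false,false,false,false,false,false,bisacodyl_rect
01000131,BetaDerm Creme,betamethasone,dermatological,,true,0.5,,false,false,false,false,false,false,betamethasone_derm
01000132,PanthoDerm Creme,dexpanthenol,dermatological,,false,50,,false,false,false,false,false,false,dexpanthenol_derm
01000141,AmoxiSaft TS,amoxicillin,liquid_oral,dry_syrup,true,250,,false,false,false,false,false,false,amoxicillin_oral
01000142,VigantOel Tropfen,colecalciferol,liquid_oral,oral_drops,false,0.025,,false,false,false,false,false,false,colecalciferol_oral
01000151,CiproOtal,ciprofloxacin,otological,,true,2,,false,false,false,false,false,false,ciprofloxacin_oto
01000161,ClotriVag 100,clotrimazole,vaginal,,false,100,,false,false,false,false,false,false,clotrimazole_vag
01000171,KaliLiquid,potassium chloride,liquid_oral,liquid_measuring_device,true,600,,false,true,false,false,false,false,potassium_oral
01000181,NitroLing Spray,glyceryl trinitrate,other,,true,0.4,,false,false,true,false,false,false,gtn_sl
01000191,CoumaTab 5,warfarin,solid_oral,,true,5,,true,false,false,true,false,false,warfarin_oral
01000201,ParaTab 500,paracetamol,solid_oral,,false,500,,true,false,false,false,false,false,paracetamol_oral
01000202,ParaBrand 500,paracetamol,solid_oral,,false,500,,true,false,false,false,false,false,paracetamol_oral
01000211,AtorvaStad 20,atorvastatin,solid_oral,,true,20,,false,false,false,false,false,false,atorvastatin_oral
01000212,LisiHexal 10,lisinopril,solid_oral,,true,10,,true,false,false,false,false,false,lisinopril_oral
01000213,ThyroBene 100,levothyroxine,solid_oral,,true,0.1,,false,false,false,false,false,false,levothyroxine_oral
01000214,OmepDura 20,omeprazole,solid_oral,,true,20,,false,false,false,false,false,false,omeprazole_oral
01000215,SertraStad 50,sertraline,solid_oral,,true,50,,true,false,false,false,false,false,sertraline_oral
01000216,BisoBene 5,bisoprolol,solid_oral,,true,5,,true,false,false,false,false,false,bisoprolol_oral
01000217,AlloHexal 100,allopurinol,solid_oral,,true,100,,true,false,false,false,false,false,allopurinol_oral
01000218,SimvaStad 20,simvastatin,solid_oral,,true,20,,false,false,false,false,false,false,simvastatin_oral
01000219,CandeBene 8,candesartan,solid_oral,,true,8,,true,false,false,false,false,false,candesartan_oral
01000220,DonepHexal 5,donepezil,solid_oral,,true,5,,false,false,false,false,false,false,donepezil_oral
01000221,MetfoDura 500,metformin,solid_oral,,true,500,,false,false,false,false,false,false,metformin_oral
01000222,PantoStad 40,pantoprazole,solid_oral,,true,40,,false,false,false,false,false,false,pantoprazole_oral
01000223,CetiHexal 10,cetirizine,solid_oral,,false,10,,true,false,false,false,false,false,cetirizine_oral
01000224,DoxaBene 4,doxazosin,solid_oral,,true,4,,true,false,false,false,false,false,doxazosin_oral
01000225,GabaStad 300,gabapentin,solid_oral,,true,300,,false,false,false,false,false,false,gabapentin_oral
01000226,TamsuDura 0.4,tamsulosin,solid_oral,,true,0.4,,false,false,false,false,false,false,tamsulosin_oral
01000227,ToraHexal 5,torasemide,solid_oral,,true,5,,true,false,false,false,false,false,torasemide_oral
01000228,SpiroBene 25,spironolactone,solid_oral,,true,25,,true,false,false,false,false,false,spironolactone_oral
01000229,ClopiStad 75,clopidogrel,solid_oral,,true,75,,false,false,false,false,false,false,clopidogrel_oral
01000230,PrednisoStad 5,prednisolone,solid_oral,,true,5,,true,false,false,false,false,false,prednisolone_oral
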