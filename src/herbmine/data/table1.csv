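material_id,scientific_name,family,local_name,part_used,property_raw,effect_category,dose_min_g,dose_max_g,pharm_tags,rfc_printed
AS,Angelica sinensis (Oliv.) Diels,Umbelliferae,Dang Gui (當歸),Roots,Warm; sweet and pungent,blood-tonifying,5,15,antianemic;anti-inflammatory;analgesic;antioxidant,0.96
LiC,Ligusticum chuanxiong Hort,Umbelliferae,Chuan Qiong (川芎),Rhizome,Warm; pungent,blood-activating and stasis-dispelling,3,10,anti-inflammatory;antioxidant,0.95
RG,Rehmannia glutinosa Libosch,Scrophulariaceae,Di Huang (地黃),Roots,Cold; sweet and bitter,heat-clearing and blood-cooling,9,30,anti-inflammatory;antioxidant;antihyperglycemic,0.79
PL,Paeonia lactiflora Pall,Ranunculaceae,Bai Shao (白芍),Roots,Mild cold; bitter and sour,blood-tonifying,6,15,anti-inflammatory;antioxidant;analgesic;antitumor;neuroprotective,0.71
HP,Hedysarum polybotrys Hand.-Mazz,Leguminosae,Hong Qi (紅耆),Roots,Mild warm; sweet,qi-tonifying,9,30,antiulcer,0.68
LyC,Lycium chinense Mill,Solanaceae,Gou Qi Zi (枸杞子),Ripe fruit,Neutral; sweet,yin-tonifying,6,15,antioxidant;immunomodulatory;antitumor;neuroprotective;hepatoprotective,0.64
CCT,Cinnamomum cassia (L.) J.Presl,Lauraceae,Gui Zhi (桂枝),Twig,Warm; pungent and sweet,pungent-warm exterior-releasing,3,10,antitumor;anti-inflammatory;analgesic;antibacterial;antiviral;neuroprotective,0.59
GU,Glycyrrhiza uralensis Fisch,Leguminosae,Gan Cao (甘草),Roots and rhizome,Neutral; sweet,qi-tonifying,2,11.5,antiulcer;analgesic;antioxidant;anti-inflammatory;antitumor;antiviral;hepatoprotective;antihyperglycemic,0.45
CP,Codonopsis pilosula (Franch.) Nannf.,Campanulaceae,Dang Shen (黨參),Roots,Neutral; sweet,qi-tonifying,9,30,immunomodulatory;antitumor;antioxidant;neuroprotective;antiviral;anti-inflammatory;antihyperglycemic;hepatoprotective,0.4
EU,Eucommia ulmoides Oliv,Eucommiaceae,Du Zhong (杜仲),Bark of trunk,Warm; sweet,yang-tonifying,6,15,antihypertensive;antihyperglycemic;antioxidant;antitumor;immunomodulatory;neuroprotective,0.38
ZJ,Ziziphus jujuba Mill,Rhamnaceae,Da Zao (紅棗),Ripe fruit,Warm; sweet,qi-tonifying,6,30,immunomodulatory;antioxidant;antitumor;hepatoprotective;antihyperglycemic,0.36
OI,Oroxylum indicum (L.) Benth. ex Kurz,Bignoniaceae,Mu Hu Dieh (木蝴蝶),Seeds,Cool; bitter and sweet,heat-clearing and detoxicating,1,4,antitumor;antibacterial;antihyperglycemic;anti-inflammatory,0.31
ZJH,Ziziphus jujuba Mill,Rhamnaceae,Hei Zao (黑棗),Ripe fruit,Warm; sweet,qi-tonifying,6,30,immunomodulatory;antioxidant;antitumor;hepatoprotective;antihyperglycemic,0.3
CCB,Cinnamomum cassia (L.) J.Presl,Lauraceae,Rou Gui (肉桂),Bark of trunk,Highly hot; pungent and sweet,interior-warming,1,5,antitumor;anti-inflammatory;analgesic;antibacterial;antiviral;neuroprotective,0.28
PC,Poria cocos (Schwein.) F.A.Wolf,Polyporaceae,Fu Ling (茯苓),Sclerotium,Neutral; sweet and bland,dampness-draining and diuretic,9,30,antitumor;immunomodulatory;anti-inflammatory;antioxidant;antihyperglycemic,0.27
AM,Atractylodes macrocephala Koidz,Compositae,Bai Zhu (白朮),Rhizome,Warm; bitter and sweet,qi-tonifying,6,15,antitumor;neuroprotective;anti-inflammatory;hepatoprotective,0.25
PP,Prunus persica (L.) Batsch,Rosaceae,Tao Ren (桃仁),Ripe seed,Neutral; bitter and sweet,blood-activating and stasis-dispelling,4.5,10,anti-inflammatory;antinociceptive;antipyretic,0.21
ZO,Zingiber officinale Roscoe,Zingiberaceae,Gan Jiang (乾薑),Rhizome,Hot; pungent,interior-warming,3,9,antiemetic;antibacterial;antitumor;anti-inflammatory;antioxidant,0.17
CR,Cyperus rotundus L,Cyperaceae,Xiang Fu (香附),Rhizome,"Neutral; pungent, mild bitter and mild sweet.",qi-regulating,6,11.5,analgesic;anti-inflammatory;antioxidant;antiviral;hepatoprotective;neuroprotective;antihyperglycemic,0.15
LJ,Leonurus japonicus Houtt,Labiatae,Yi Mu Cao (益母草),Aerial part,Mild cold; bitter and pungent,blood-activating and stasis-dispelling,9,30,antioxidant;anti-inflammatory,0.14
CaT,Carthamus tinctorius L,Compositae,Hong Hua (紅花),Tubular flower,Warm; pungent,blood-activating and stasis-dispelling,3,10,cardioprotective;neuroprotective;antitumor;anticoagulant,0.1
CY,Corydalis yanhusuo W.T. Wang,Papaveraceae,Yan Hu Su (延胡索),Tuber,Warm; pungent and bitter,blood-activating and stasis-dispelling,3,12,analgesic;antianxiety;antiarrhythmic;antiulcer,0.1
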