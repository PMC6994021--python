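canonical,variant,adjuvant_flag
ipilimumab,yervoy,false
ipilimumab,ipi,false
nivolumab,opdivo,false
nivolumab,nivo,false
pembrolizumab,keytruda,false
pembrolizumab,pembro,false
vemurafenib,zelboraf,false
dabrafenib,tafinlar,false
trametinib,mekinist,false
cobimetinib,cotellic,false
binimetinib,mektovi,false
encorafenib,braftovi,false
temozolomide,temodar,false
temozolomide,temodal,false
temozolomide,tmz,false
dacarbazine,dtic,false
interferon,intron a,true
interferon,sylatron,true
interferon,peginterferon,true
interferon,interferon-alfa,true
docetaxel,taxotere,true
paclitaxel,taxol,false
paclitaxel,abraxane,false
carboplatin,paraplatin,false
carboplatin,carbo,false
interleukin-2,proleukin,false
interleukin-2,il-2,false
interleukin-2,aldesleukin,false
interleukin-2,interleukin 2,false
talimogene laherparepvec,t-vec,false
talimogene laherparepvec,tvec,false
talimogene laherparepvec,imlygic,false
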