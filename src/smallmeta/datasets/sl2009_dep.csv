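study_id,available_data,measure,intervention,n_t,n_c,n_total,r
Bedard.2003.1,prepost-msds,BDI-II,Mindfulness,10,3,13,.24
Cheavens.2006.1,prepost-msds,CES-D,Hope therapy,16,16,32,.23
Davis.2004.1,post-msds,SZD,Life Review therapy,7,7,14,.81
Fava.1998.1,prepost-msds,CID-DEP,Well-being therapy,10,10,20,.53
Fava.1998.1,prepost-msds,SQ-DEP,Well-being therapy,10,10,20,.04
Fava.2005.1,prepost-msds,CID-DEP,Well-being therapy,8,8,16,.28
Fava.2005.1,prepost-msds,SQ-DEP,Well-being therapy,8,8,16,.22
Fordyce.1983.4,post-msds,DAC,Fundamentals,64,39,103,.14
Fordyce.1983.6,prepost-msds,DAC,Fundamentals,14,13,27,.05
Fordyce.1983.6,prepost-msds,DAC,Fundamentals—personality,10,13,23,0
Fordyce.1983.6,prepost-msds,DAC,Fundamentals—attitudes,12,13,25,.18
Fordyce.1983.6,prepost-msds,DAC,Fundamentals—lifestyle,8,13,21,.26
Freedman.1996.1,prepost-msds,BDI,Forgiveness,6,6,12,.52
Grossman.2007.1,prepost-msds,HADS-D,Mindfulness,39,13,52,.21
Lichter.1980.2,prepost-msds,BDI,Positive feeling statements,25,23,48,.20
Lin.2004.1,prepost-msds,BDI-II,Forgiveness therapy,14,14,28,.66
Reed.2006.1,prepost-msds,BDI-II,Forgiveness therapy,10,10,20,.61
Ruini.2006.1,prepost-msds,SQ-DEP,Well-being therapy,57,54,111,-.12
Seligman.2004.1,post-cohend,CES-D,Unspecified,102,83,185,-.15
Seligman.2005.1,prepost-msds,CES-D,Gratitude visit,80,70,150,.16
Seligman.2005.1,prepost-msds,CES-D,Three good things,59,70,129,.10
Seligman.2005.1,prepost-msds,CES-D,You at your best,68,70,138,.10
Seligman.2005.1,prepost-msds,CES-D,Signature strengths,66,70,136,.07
Seligman.2005.1,prepost-msds,CES-D,Identifying signature strengths,68,70,138,.03
Seligman.2006.1,prepost-msds,BDI-II,Positive psychotherapy,14,20,34,.22
Seligman.2006.2,prepost-msds,ZSRS,Positive psychotherapy,11,9,20,.47
Seligman.2006.2,post-msds,HRSD,Positive psychotherapy,11,9,20,.59
Smith.1995.1,prepost-difmsds,BDI,Personal happiness,17,12,29,.39
Smith.1995.1,prepost-difmsds,BDI,Personal happiness w/ meditation,7,12,19,.60
Surawy.2005.1,prepost-msds,HADS-D,Mindfulness,9,8,17,.19
Zautra.2008.1a,prepost-msds,DEPS-NS,Mindfulness,41,30,71,-.03
Zautra.2008.1b,prepost-msds,DEPS-NS,Mindfulness,6,14,20,.31
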