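study_id,available_data,measure,intervention,n_t,n_c,n_total,r
Abbott.2009.1,prepost-msds,AHI,Reslience program,26,27,53,-.02
Cheavens.2006.1,prepost-msds,TSHS,Hope therapy,16,16,32,.17
Emmons.2003.3,post-anovaF,Connection w/others,Gratitude,33,32,65,.39
Fava.1998.1,prepost-msds,PWB-AU,Well-being therapy,10,10,20,.12
Fava.1998.1,prepost-msds,PWB-EM,Well-being therapy,10,10,20,.20
Fava.1998.1,prepost-msds,PWB-PG,Well-being therapy,10,10,20,.22
Fava.1998.1,prepost-msds,PWB-PR,Well-being therapy,10,10,20,.22
Fava.1998.1,prepost-msds,PWB-PL,Well-being therapy,10,10,20,.01
Fava.1998.1,prepost-msds,PWB-SA,Well-being therapy,10,10,20,.18
Fava.2005.1,prepost-msds,PWB-AU,Well-being therapy,8,8,16,.51
Fava.2005.1,prepost-msds,PWB-EM,Well-being therapy,8,8,16,.54
Fava.2005.1,prepost-msds,PWB-PG,Well-being therapy,8,8,16,.63
Fava.2005.1,prepost-msds,PWB-PR,Well-being therapy,8,8,16,.40
Fava.2005.1,prepost-msds,PWB-PL,Well-being therapy,8,8,16,.62
Fava.2005.1,prepost-msds,PWB-SA,Well-being therapy,8,8,16,.58
Feldman.2012.1,prepost-msds,GSHS-A,Hope-based,32,32,64,-.01
Feldman.2012.1,prepost-msds,GSHS-P,Hope-based,32,32,64,.13
Feldman.2012.1,prepost-msds,PIL,Hope-based,32,32,64,.04
Friesqijk.2006.1,prepost-msds,MAS,Self-management,79,86,165,.06
Gander.2013.1,prepost-msds,AHI,Gratitude visit,61,63,124,.05
Gander.2013.1,prepost-msds,AHI,Three good things,87,63,150,.03
Gander.2013.1,prepost-msds,AHI,Signature strengths,73,63,136,.05
Gander.2013.1,prepost-msds,AHI,Three good things/2 weeks,64,63,127,.12
Gander.2013.1,prepost-msds,AHI,Gratitude & 3 good things,60,63,123,.15
Gander.2013.1,prepost-msds,AHI,Three funny things,55,63,118,-.01
Gander.2013.1,prepost-msds,AHI,Counting kindness,62,63,125,.06
Gander.2013.1,prepost-msds,AHI,Gift of time,55,63,118,-.01
Gander.2013.1,prepost-msds,AHI,One door closes . . .,42,63,105,.03
Green.2006.1,prepost-msds,HTS-C,Solution coaching,25,24,49,.18
Green.2006.1,prepost-msds,PWB-PG,Solution coaching,25,25,50,.13
Green.2006.1,prepost-msds,PWB-EM,Solution coaching,25,25,50,.34
Green.2006.1,prepost-msds,PWB-AU,Solution coaching,25,25,50,.03
Green.2006.1,prepost-msds,PWB-PR,Solution coaching,25,25,50,.35
Green.2006.1,prepost-msds,PWB-PL,Solution coaching,25,25,50,.50
Layous.2013.1,prepost-difmsds,NS-NS,Best possible self,81,38,119,.06
Luthans.2008.1,prepost-msds,PCQ,PsyCap,187,177,364,.05
Luthans.2010.1,prepost-ancovaF,PCQ,PsyCap,153,89,242,.21
Mitchell.2009.1,prepost-msds,OTH-P,Signature strengths,14,23,37,.26
Mitchell.2009.1,prepost-msds,OTH-E,Signature strengths,17,23,40,.18
Mitchell.2009.1,prepost-msds,OTH-M,Signature strengths,17,23,40,-.02
Mongrain.2011.1,prepost-msds,SHIS,Self-compassion,237,237,474,.02
Mongrain.2012.1,prepost-msds,SHI,Positive early memories,87,81,168,-.01
Mongrain.2012.1,prepost-msds,SHI,Three good things,102,81,183,.02
Mongrain.2012.1,prepost-msds,SHI,Signature strengths,74,81,155,.06
Page.2013.1,prepost-msds,PWB,Wellness,23,14,37,.11
Seligman.2006.2,prepost-msds,PPTI,Positive psychotherapy,11,9,20,.40
Spence.2007.1,prepost-msds,PWB-AU,Professional coaching,20,17,37,.40
Spence.2007.1,prepost-msds,PWB-EM,Professional coaching,20,17,37,.13
Spence.2007.1,prepost-msds,PWB-PR,Professional coaching,20,17,37,.07
Spence.2007.1,prepost-msds,PWB-PL,Professional coaching,20,17,37,.35
Spence.2007.1,prepost-msds,PWB-PG,Professional coaching,20,17,37,.35
Spence.2007.1,prepost-msds,PWB-SA,Professional coaching,20,17,37,.28
Spence.2007.1,prepost-msds,PWB-AU,Peer coaching,20,17,37,.28
Spence.2007.1,prepost-msds,PWB-EM,Peer coaching,20,17,37,.14
Spence.2007.1,prepost-msds,PWB-PR,Peer coaching,20,17,37,.12
Spence.2007.1,prepost-msds,PWB-PL,Peer coaching,20,17,37,.43
Spence.2007.1,prepost-msds,PWB-PG,Peer coaching,20,17,37,.30
Spence.2007.1,prepost-msds,PWB-SA,Peer coaching,20,17,37,.33
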