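analyte,trophic_level,endpoint,value_mg_L,qualifier,class,source
BPA,algae,EC50,2.5,,acute,lit
BPA,invertebrate,EC50,10,,acute,lit
BPA,fish,LC50,4.6,,acute,lit
HQ,algae,LC50,1,range_lower,acute,lit
HQ,invertebrate,LC50,0.33,,acute,lit
HQ,fish,LC50,0.638,,acute,lit
BQ,algae,EC50,1.5,,acute,lit
BQ,invertebrate,EC50,0.059,,acute,lit
BQ,fish,LC50,0.638,,acute,lit
RE,algae,LC50,97,,acute,lit
RE,invertebrate,LC50,1.0,,acute,lit
RE,fish,LC50,53.4,,acute,lit
BPA,algae,NOEC,1.17,,chronic,lit
BPA,invertebrate,NOEC,4.11,,chronic,lit
BPA,fish,NOEC,3.64,,chronic,lit
HQ,algae,NOEC,0.019,,chronic,lit
HQ,invertebrate,NOEC,0.057,,chronic,lit
HQ,fish,NOEC,0.066,lower_bound,chronic,lit
BQ,algae,NOEC,0.019,,chronic,lit
BQ,invertebrate,NOEC,0.0057,,chronic,lit
BQ,fish,NOEC,0.066,lower_bound,chronic,lit
RE,invertebrate,NOEC,0.172,,chronic,lit
RE,fish,NOEC,1.1,lower_bound,chronic,lit
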